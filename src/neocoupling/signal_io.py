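"""Recording container and CSV side-table I/O.

The recording container is deliberately simple: a flat little-endian float32
binary file holding the samples sample-major (all channels of sample 0, then
all channels of sample 1, ...), next to a JSON sidecar with the same stem and
a ``.json`` suffix that declares the sampling rate, start time and ordered
per-channel metadata. ``write_recording`` and ``read_recording`` are exact
inverses on valid inputs.

Side tables (stimulus events, sorted spikes, nose tracking, ultrasonic
vocalization calls) are plain CSV files with fixed, mandatory header rows.
Validation is total: every invariant violation raises a typed error naming
the first offending row.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CorruptionError, FormatError, ParameterError, ValidationError

AREAS = ("OB", "CA1", "PFC")

EVENT_KINDS = ("odor_on", "odor_off", "injection", "epoch_start", "epoch_end")

#: mandatory CSV columns per schema
CSV_SCHEMAS = {
    "event": ("kind", "t", "label"),
    "spike": ("unit_id", "channel", "t"),
    "track": ("frame", "x_cm", "y_cm", "likelihood"),
    "call": ("t_on", "t_off", "peak_freq_khz"),
}

#: detector band for ultrasonic calls, kHz
USV_BAND_KHZ = (25.0, 125.0)


@dataclass(frozen=True)
class ChannelMeta:
    """Metadata for one recording site: brain area, depth and probe position."""

    area: str
    depth_um: float
    index: int

    def __post_init__(self):
        if self.area not in AREAS:
            raise ValidationError(f"unknown area {self.area!r}; expected one of {AREAS}")


@dataclass
class Recording:
    """A validated multi-channel extracellular recording.

    ``samples`` is a 2-D array [n_channels x n_samples] in arbitrary voltage
    units; channel order is shallow-to-deep within each probe. ``t0`` is the
    recording start time in seconds.
    """

    samples: np.ndarray
    fs: float
    channels: list[ChannelMeta]
    t0: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValidationError("samples must be 2-D [n_channels x n_samples]")
        if self.fs <= 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")
        if self.samples.shape[0] != len(self.channels):
            raise ValidationError(
                f"{self.samples.shape[0]} sample rows but {len(self.channels)} "
                "channel metadata entries"
            )
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValidationError("samples contain NaN or Inf")
        # depth must increase strictly with probe index within each area
        for area in AREAS:
            metas = [c for c in self.channels if c.area == area]
            metas.sort(key=lambda c: c.index)
            depths = [c.depth_um for c in metas]
            if any(b <= a for a, b in zip(depths, depths[1:])):
                raise ValidationError(
                    f"depth_um not strictly increasing with index on the {area} probe"
                )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording duration in seconds."""
        return self.n_samples / self.fs

    def channel_indices(self, area: str) -> list[int]:
        """Row indices in ``samples`` belonging to ``area``, shallow to deep."""
        return [i for i, c in enumerate(self.channels) if c.area == area]

    def get_channel(self, i: int) -> np.ndarray:
        return self.samples[i]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording(rec: Recording, path) -> None:
    """Write ``rec`` as flat float32-LE binary plus JSON sidecar.

    ``read_recording`` inverts this exactly for float32-representable data;
    the synthetic generator and all fixtures store float32.
    """
    path = Path(path)
    try:
        rec.samples.T.astype("<f4").tofile(path)
    except OSError as e:  # pragma: no cover - filesystem dependent
        raise FormatError(f"cannot write recording binary to {path}: {e}") from e
    sidecar = {
        "fs": rec.fs,
        "t0": rec.t0,
        "n_channels": rec.n_channels,
        "channels": [
            {"area": c.area, "depth_um": c.depth_um, "index": c.index}
            for c in rec.channels
        ],
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_recording(path) -> Recording:
    """Read and validate a recording container written by :func:`write_recording`."""
    path = Path(path)
    sidecar_path = _sidecar_path(path)
    if not path.exists():
        raise FormatError(f"recording binary not found: {path}")
    if not sidecar_path.exists():
        raise FormatError(f"sidecar not found: {sidecar_path}")
    try:
        meta = json.loads(sidecar_path.read_text())
        fs = float(meta["fs"])
        t0 = float(meta.get("t0", 0.0))
        channels = [
            ChannelMeta(area=c["area"], depth_um=float(c["depth_um"]), index=int(c["index"]))
            for c in meta["channels"]
        ]
    except (KeyError, TypeError, ValueError, json.JSONDecodeError) as e:
        raise FormatError(f"malformed sidecar {sidecar_path}: {e}") from e
    k = len(channels)
    if k == 0:
        raise FormatError(f"sidecar {sidecar_path} declares no channels")
    n_bytes = path.stat().st_size
    if n_bytes % (4 * k) != 0:
        raise CorruptionError(
            f"{path}: file size {n_bytes} B is not a multiple of 4 x {k} channels"
        )
    raw = np.fromfile(path, dtype="<f4")
    samples = raw.reshape(-1, k).T
    return Recording(samples=samples, fs=fs, channels=channels, t0=t0)


# ---------------------------------------------------------------------------
# CSV side tables


@dataclass
class EventTable:
    """Stimulus / manipulation events: (kind, t seconds, free-text label)."""

    df: pd.DataFrame

    def __post_init__(self):
        df = self.df
        bad = ~df["kind"].isin(EVENT_KINDS)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(f"row {row}: unknown event kind {df['kind'].iloc[row]!r}")
        t = df["t"].to_numpy(dtype=float)
        if (t < 0).any():
            row = int(np.flatnonzero(t < 0)[0])
            raise ValidationError(f"row {row}: negative event time {t[row]}")
        if (np.diff(t) < 0).any():
            row = int(np.flatnonzero(np.diff(t) < 0)[0]) + 1
            raise ValidationError(f"row {row}: event times not sorted ascending")
        # odor_on / odor_off must alternate per label, starting with odor_on
        for label, grp in df[df["kind"].isin(["odor_on", "odor_off"])].groupby("label"):
            kinds = grp["kind"].tolist()
            expected = ["odor_on", "odor_off"] * ((len(kinds) + 1) // 2)
            if kinds != expected[: len(kinds)]:
                raise ValidationError(
                    f"odor_on/odor_off do not alternate for label {label!r}"
                )

    def windows(self, label=None) -> list[tuple[float, float]]:
        """Paired (odor_on, odor_off) windows, optionally for one label."""
        df = self.df[self.df["kind"].isin(["odor_on", "odor_off"])]
        if label is not None:
            df = df[df["label"] == label]
        t = df["t"].to_numpy(dtype=float)
        return [(t[i], t[i + 1]) for i in range(0, len(t) - 1, 2)]


@dataclass
class SpikeTable:
    """Sorted single-unit spikes: (unit_id, probe channel, time in seconds)."""

    df: pd.DataFrame

    def __post_init__(self):
        t = self.df["t"].to_numpy(dtype=float)
        if (t < 0).any():
            row = int(np.flatnonzero(t < 0)[0])
            raise ValidationError(f"row {row}: negative spike time {t[row]}")

    def validate_against(self, rec: Recording) -> None:
        """Check channel indices and times against a paired recording."""
        probe = {c.index for c in rec.channels}
        ch = self.df["channel"].to_numpy(dtype=int)
        bad = ~np.isin(ch, list(probe))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValidationError(f"row {row}: spike channel {ch[row]} not on the probe")
        t = self.df["t"].to_numpy(dtype=float)
        end = rec.t0 + rec.duration
        if ((t < rec.t0) | (t > end)).any():
            row = int(np.flatnonzero((t < rec.t0) | (t > end))[0])
            raise ValidationError(
                f"row {row}: spike time {t[row]} outside recording [{rec.t0}, {end}]"
            )

    def unit_ids(self) -> np.ndarray:
        return np.unique(self.df["unit_id"].to_numpy(dtype=int))


@dataclass
class TrackTable:
    """Nose-tracking output: (frame, x_cm, y_cm, likelihood) at ``fps`` frames/s."""

    df: pd.DataFrame
    fps: float

    def __post_init__(self):
        if self.fps is None or self.fps <= 0:
            raise ParameterError(f"fps must be positive, got {self.fps}")
        frames = self.df["frame"].to_numpy(dtype=int)
        if (np.diff(frames) <= 0).any():
            row = int(np.flatnonzero(np.diff(frames) <= 0)[0]) + 1
            raise ValidationError(f"row {row}: frames not strictly increasing")
        lk = self.df["likelihood"].to_numpy(dtype=float)
        bad = (lk < 0) | (lk > 1)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValidationError(f"row {row}: likelihood {lk[row]} outside [0, 1]")

    @property
    def duration(self) -> float:
        return len(self.df) / self.fps


@dataclass
class CallTable:
    """Ultrasonic vocalization calls: (t_on, t_off, peak_freq_khz)."""

    df: pd.DataFrame

    def __post_init__(self):
        t_on = self.df["t_on"].to_numpy(dtype=float)
        t_off = self.df["t_off"].to_numpy(dtype=float)
        bad = t_off <= t_on
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValidationError(f"row {row}: t_off {t_off[row]} <= t_on {t_on[row]}")
        if (np.diff(t_on) < 0).any():
            row = int(np.flatnonzero(np.diff(t_on) < 0)[0]) + 1
            raise ValidationError(f"row {row}: calls not sorted by t_on")
        pf = self.df["peak_freq_khz"].to_numpy(dtype=float)
        lo, hi = USV_BAND_KHZ
        bad = (pf < lo) | (pf > hi)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                f"row {row}: peak frequency {pf[row]} kHz outside detector band {USV_BAND_KHZ}"
            )


_TABLE_TYPES = {
    "event": EventTable,
    "spike": SpikeTable,
    "track": TrackTable,
    "call": CallTable,
}


def read_csv_table(path, schema: str, fps: float | None = None):
    """Read one of the four side-table CSVs and validate it.

    Parameters
    ----------
    path : path-like
        CSV file with a mandatory header row.
    schema : {"event", "spike", "track", "call"}
        Which table type to expect.
    fps : float, optional
        Frames per second; required for (and only for) the ``track`` schema,
        since the CSV itself stores frame numbers, not times.
    """
    if schema not in CSV_SCHEMAS:
        raise ParameterError(f"unknown schema {schema!r}; expected one of {sorted(CSV_SCHEMAS)}")
    path = Path(path)
    if not path.exists():
        raise FormatError(f"CSV not found: {path}")
    df = pd.read_csv(path)
    expected = CSV_SCHEMAS[schema]
    if tuple(df.columns) != expected:
        raise FormatError(
            f"{path}: columns {tuple(df.columns)} do not match the {schema!r} "
            f"schema {expected}"
        )
    if schema == "track":
        if fps is None:
            raise ParameterError("fps is required for track tables")
        return TrackTable(df=df, fps=fps)
    return _TABLE_TYPES[schema](df=df)


def write_csv_table(table, path) -> None:
    """Write a side table back to CSV (inverse of :func:`read_csv_table`)."""
    table.df.to_csv(path, index=False)
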