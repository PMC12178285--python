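"""Welch power spectra, band power in the RR/theta/beta bands, and the
pre/post power modulation index.

Band conventions follow the developmental-LFP literature: respiration rhythm
(RR) 2-4 Hz, theta 4-12 Hz, beta 12-30 Hz, all half-open ``[low, high)``.
Welch estimation uses Hamming-tapered, non-overlapping 2 s segments and
one-sided per-Hz density normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import LengthError, ParameterError, UndefinedValueError


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low_hz: float
    high_hz: float


RR_BAND = BandDefinition("RR", 2.0, 4.0)
THETA_BAND = BandDefinition("theta", 4.0, 12.0)
BETA_BAND = BandDefinition("beta", 12.0, 30.0)
DEFAULT_BANDS = (RR_BAND, THETA_BAND, BETA_BAND)


@dataclass
class PowerSpectrum:
    """One-sided Welch power spectral density (units^2 / Hz)."""

    freqs: np.ndarray
    power: np.ndarray
    n_segments: int
    window_s: float


@dataclass
class ModulationIndexValue:
    """Difference-over-sum contrast of post- vs pre-epoch power, in [-1, 1]."""

    mi: float
    pre_power: float
    post_power: float


def welch_psd(x, fs: float, window_s: float = 2.0, overlap: float = 0.0) -> PowerSpectrum:
    """Welch PSD with Hamming tapers over non-overlapping windows by default.

    The estimate is the mean of tapered periodograms over
    ``floor(duration / window_s)`` segments (for ``overlap=0``) and is
    Parseval-consistent: the integrated density of a zero-mean signal
    approximates its variance.
    """
    x = np.asarray(x, dtype=np.float64)
    if not 0 <= overlap < 1:
        raise ParameterError(f"overlap must be in [0, 1), got {overlap}")
    nperseg = int(round(window_s * fs))
    if nperseg < 2:
        raise ParameterError(f"window_s {window_s} too short for fs {fs}")
    if x.shape[-1] < nperseg:
        raise LengthError(
            f"input length {x.shape[-1]} shorter than one {window_s} s window"
        )
    noverlap = int(round(overlap * nperseg))
    freqs, power = sps.welch(
        x,
        fs=fs,
        window="hamming",
        nperseg=nperseg,
        noverlap=noverlap,
        detrend="constant",
        scaling="density",
    )
    step = nperseg - noverlap
    n_segments = (x.shape[-1] - noverlap) // step
    return PowerSpectrum(freqs=freqs, power=power, n_segments=n_segments, window_s=window_s)


def band_power(ps: PowerSpectrum, band: BandDefinition) -> float:
    """Trapezoidal integral of the density over ``[low_hz, high_hz)``."""
    if band.low_hz < ps.freqs[0] or band.high_hz > ps.freqs[-1]:
        raise ParameterError(
            f"band {band.name} [{band.low_hz}, {band.high_hz}) outside the "
            f"spectral grid [{ps.freqs[0]}, {ps.freqs[-1]}]"
        )
    mask = (ps.freqs >= band.low_hz) & (ps.freqs < band.high_hz)
    if mask.sum() < 2:
        raise ParameterError(
            f"band {band.name} narrower than the spectral resolution"
        )
    return float(np.trapezoid(ps.power[mask], ps.freqs[mask]))


def power_modulation_index(pre: float, post: float) -> ModulationIndexValue:
    """(post - pre) / (post + pre); undefined when both epochs have zero power."""
    if pre < 0 or post < 0:
        raise ParameterError("band powers must be non-negative")
    if pre + post == 0:
        raise UndefinedValueError("modulation index undefined for pre = post = 0")
    return ModulationIndexValue(mi=(post - pre) / (post + pre), pre_power=pre, post_power=post)


def band_power_table(
    rec,
    channel_by_area: dict[str, int],
    bands=DEFAULT_BANDS,
    window_s: float = 2.0,
    recording_id: str = "rec",
) -> pd.DataFrame:
    """Tidy per-(recording, area, band) power table for one recording.

    ``channel_by_area`` maps each area name to the row index in
    ``rec.samples`` whose LFP represents that area.
    """
    rows = []
    for area, ch in channel_by_area.items():
        ps = welch_psd(rec.get_channel(ch), rec.fs, window_s=window_s)
        for band in bands:
            rows.append(
                {
                    "recording_id": recording_id,
                    "area": area,
                    "band": band.name,
                    "power": band_power(ps, band),
                }
            )
    return pd.DataFrame(rows, columns=["recording_id", "area", "band", "power"])
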