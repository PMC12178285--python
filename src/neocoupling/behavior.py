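"""Odor-place preference and ultrasonic-vocalization (USV) scoring.

The odor-place arena is a 17.5 cm corridor with a 6.5 cm odor zone at each
end and a 4.5 cm neutral zone in the center; zone membership is decided by
the tracked nose x-coordinate. Preference for the learned (test) odor over
the control odor is the difference-over-sum of zone dwell times. Odor
detection in pups is scored by call-rate suppression: the modulation index
of call rate during versus before an odor window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, QualityError, UndefinedValueError, ValidationError
from .signal_io import CallTable, TrackTable

ZONE_TEST = "test"
ZONE_CONTROL = "control"
ZONE_NEUTRAL = "neutral"


@dataclass(frozen=True)
class ArenaGeometry:
    """Corridor arena: two end odor zones flanking a central neutral zone."""

    length_cm: float = 17.5
    zone_cm: float = 6.5
    neutral_cm: float = 4.5

    def __post_init__(self):
        if abs(2 * self.zone_cm + self.neutral_cm - self.length_cm) > 1e-9:
            raise ParameterError(
                "arena zones inconsistent: 2*zone_cm + neutral_cm must equal length_cm"
            )


@dataclass
class OccupancyResult:
    t_test: float
    t_control: float
    t_neutral: float
    n_excluded_frames: int


@dataclass
class DiscriminationIndex:
    """(t_test - t_control) / (t_test + t_control), in [-1, 1]."""

    di: float


@dataclass
class USVModulation:
    """(rate during odor - rate before) / (sum of the two), in [-1, 1]."""

    mi: float
    rate_before: float
    rate_during: float


def zone_labels(x_cm: np.ndarray, geom: ArenaGeometry, test_side: str) -> np.ndarray:
    """Zone label per x position: left zone [0, 6.5), neutral [6.5, 11),
    right zone [11, 17.5]."""
    if test_side not in ("left", "right"):
        raise ParameterError(f"test_side must be 'left' or 'right', got {test_side!r}")
    left_edge = geom.zone_cm
    right_edge = geom.zone_cm + geom.neutral_cm
    labels = np.full(x_cm.shape, ZONE_NEUTRAL, dtype=object)
    left = x_cm < left_edge
    right = x_cm >= right_edge
    labels[left] = ZONE_TEST if test_side == "left" else ZONE_CONTROL
    labels[right] = ZONE_TEST if test_side == "right" else ZONE_CONTROL
    return labels


def zone_occupancy(
    track: TrackTable,
    geom: ArenaGeometry = ArenaGeometry(),
    test_side: str = "left",
    likelihood_min: float = 0.9,
) -> OccupancyResult:
    """Dwell time per zone from a nose-tracking table.

    Frames with tracking likelihood below ``likelihood_min`` are excluded and
    counted; remaining frames map to zones by nose x and convert to seconds
    via the table's fps. Zone times plus excluded time reconstruct the
    session duration frame-exactly.
    """
    x = track.df["x_cm"].to_numpy(dtype=float)
    lk = track.df["likelihood"].to_numpy(dtype=float)
    keep = lk >= likelihood_min
    n_excluded = int((~keep).sum())
    if not keep.any():
        raise QualityError("all frames excluded by the likelihood threshold")
    x_kept = x[keep]
    if (x_kept < 0).any() or (x_kept > geom.length_cm).any():
        bad = int(np.flatnonzero((x_kept < 0) | (x_kept > geom.length_cm))[0])
        raise ValidationError(f"kept frame {bad}: nose x outside the arena")
    labels = zone_labels(x_kept, geom, test_side)
    fps = track.fps
    return OccupancyResult(
        t_test=float((labels == ZONE_TEST).sum() / fps),
        t_control=float((labels == ZONE_CONTROL).sum() / fps),
        t_neutral=float((labels == ZONE_NEUTRAL).sum() / fps),
        n_excluded_frames=n_excluded,
    )


def discrimination_index(occ: OccupancyResult) -> DiscriminationIndex:
    """Difference-over-sum of test- vs control-zone dwell time."""
    denom = occ.t_test + occ.t_control
    if denom <= 0:
        raise UndefinedValueError("discrimination index undefined: no time in odor zones")
    return DiscriminationIndex(di=(occ.t_test - occ.t_control) / denom)


def usv_modulation_index(
    calls: CallTable,
    odor_window: tuple[float, float],
    baseline_window: tuple[float, float],
) -> USVModulation:
    """Call-rate modulation index for one odor presentation.

    Call onsets are counted inside each window (half-open ``[start, end)``),
    converted to rates, and contrasted as (during - before)/(during + before).
    """
    for name, (a, b) in (("odor", odor_window), ("baseline", baseline_window)):
        if b <= a:
            raise ParameterError(f"{name} window must have positive length")
    a0, a1 = baseline_window
    b0, b1 = odor_window
    if max(a0, b0) < min(a1, b1):
        raise ParameterError("odor and baseline windows must be disjoint")
    t_on = calls.df["t_on"].to_numpy(dtype=float)
    rate_before = ((t_on >= a0) & (t_on < a1)).sum() / (a1 - a0)
    rate_during = ((t_on >= b0) & (t_on < b1)).sum() / (b1 - b0)
    if rate_before + rate_during == 0:
        raise UndefinedValueError("modulation index undefined: no calls in either window")
    return USVModulation(
        mi=float((rate_during - rate_before) / (rate_during + rate_before)),
        rate_before=float(rate_before),
        rate_during=float(rate_during),
    )
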