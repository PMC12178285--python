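"""Olfactory-bulb layer assignment and firing rates.

The mitral cell layer (MCL) is localized electrophysiologically: the 2-4 Hz
respiration rhythm (RR) reverses LFP polarity at the MCL, so on a linear
probe the reversal shows up as a single adjacent channel pair whose RR-band
signals are anticorrelated. Units within +-1 channel of the reversal are
treated as MCL units; units more than 3 channels deeper are granule cell
layer (GCL) units; channels in between stay unassigned by design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DetectionError, LengthError, ParameterError
from .preprocess import FilterSpec, bandpass
from .signal_io import Recording, SpikeTable

LAYER_MCL = "MCL"
LAYER_GCL = "GCL"
LAYER_UNASSIGNED = "unassigned"


@dataclass
class LayerAssignment:
    mcl_channel: int
    unit_layers: dict[int, str]


def detect_mcl_channel(rec: Recording, band=(2.0, 4.0)) -> int:
    """Locate the RR polarity reversal on the OB probe.

    Every OB channel is filtered to the RR band; the Pearson correlation of
    each adjacent channel pair is computed, and the unique anticorrelated
    pair marks the reversal. Returns the probe index of the shallower
    channel of that pair. Zero or multiple anticorrelated pairs raise
    :class:`DetectionError` with the correlation profile attached.
    """
    ob_rows = rec.channel_indices("OB")
    if len(ob_rows) < 8:
        raise ParameterError(f"need >= 8 OB channels, got {len(ob_rows)}")
    if rec.duration < 60.0:
        raise LengthError(f"need >= 60 s of data, got {rec.duration:.1f} s")
    spec = FilterSpec(band[0], band[1])
    rr = np.stack([bandpass(rec.get_channel(i), rec.fs, spec) for i in ob_rows])
    corrs = np.array(
        [np.corrcoef(rr[i], rr[i + 1])[0, 1] for i in range(len(ob_rows) - 1)]
    )
    negative = np.flatnonzero(corrs < 0)
    if len(negative) != 1:
        raise DetectionError(
            f"expected exactly one polarity reversal, found {len(negative)}",
            diagnostics={"adjacent_correlations": corrs},
        )
    return rec.channels[ob_rows[int(negative[0])]].index


def assign_units_to_layers(spikes: SpikeTable, mcl_channel: int) -> LayerAssignment:
    """Assign each unit to MCL / GCL / unassigned by its probe channel.

    Channels in ``[mcl-1, mcl+1]`` are MCL; channels ``> mcl+3`` (deeper,
    toward the granule cell layer) are GCL; the two channels in between are
    deliberately left unassigned so the layer rules never overlap.
    """
    unit_layers: dict[int, str] = {}
    for unit_id, grp in spikes.df.groupby("unit_id"):
        ch = int(grp["channel"].mode().iloc[0])
        if abs(ch - mcl_channel) <= 1:
            layer = LAYER_MCL
        elif ch > mcl_channel + 3:
            layer = LAYER_GCL
        else:
            layer = LAYER_UNASSIGNED
        unit_layers[int(unit_id)] = layer
    return LayerAssignment(mcl_channel=mcl_channel, unit_layers=unit_layers)


def unit_firing_rates(
    spikes: SpikeTable,
    duration: float,
    unit_ids=None,
    layers: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Per-unit firing rate table (unit_id, layer, rate_hz).

    ``unit_ids`` may list units that fired no spikes; they are retained with
    rate 0. ``layers`` optionally maps unit ids to layer/area labels.
    """
    if duration <= 0:
        raise ParameterError(f"duration must be positive, got {duration}")
    counts = spikes.df.groupby("unit_id").size()
    ids = set(counts.index.astype(int))
    if unit_ids is not None:
        ids |= {int(u) for u in unit_ids}
    rows = []
    for u in sorted(ids):
        rate = counts.get(u, 0) / duration
        layer = (layers or {}).get(u, LAYER_UNASSIGNED)
        rows.append({"unit_id": u, "layer": layer, "rate_hz": float(rate)})
    return pd.DataFrame(rows, columns=["unit_id", "layer", "rate_hz"])
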