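"""Ground-truth synthetic data emulating neonatal OB/CA1/PFC recordings.

The generator reproduces the statistical structure the analysis pipeline
assumes, with every generating parameter recorded so each stage can be
verified by parameter recovery:

* 16-channel OB probe with a dominant, noise-driven 2-4 Hz respiration
  rhythm (RR) that flips polarity below the mitral cell layer channel, plus
  weaker theta/beta narrowband components and 1/f noise per channel;
* continuous OB activity versus discontinuous (burst-gated) CA1/PFC
  activity, with directed OB->CA1, OB->PFC and CA1->PFC coupling implemented
  as delayed, scaled copies of the OB oscillation plus independent noise;
* a fast oscillation in CA1/PFC whose envelope is modulated by the OB RR
  phase with configurable depth (phase-amplitude coupling ground truth);
* phase-locked inhomogeneous Poisson spiking per layer/area;
* behavior sessions: a biased reflected random walk over the odor-place
  arena and Poisson call trains suppressed during odor windows.

All randomness flows from the single config seed; the same config produces
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import signal as sps

from .behavior import ArenaGeometry, zone_labels, ZONE_TEST, ZONE_CONTROL, ZONE_NEUTRAL
from .errors import ConfigError
from .preprocess import FilterSpec, analytic_signal, bandpass
from .signal_io import CallTable, ChannelMeta, Recording, SpikeTable, TrackTable


@dataclass(frozen=True)
class CouplingSpec:
    """Directed gains and integer sample delays between areas."""

    gain_ob_ca1: float = 0.6
    delay_ob_ca1: int = 20
    gain_ob_pfc: float = 0.4
    delay_ob_pfc: int = 30
    gain_ca1_pfc: float = 0.3
    delay_ca1_pfc: int = 10


@dataclass(frozen=True)
class SyntheticConfig:
    """All generator knobs; defaults are the reference study conditions."""

    fs: float = 1000.0
    duration_s: float = 120.0
    n_ob_channels: int = 16
    mcl_index: int = 8
    rr_freq_hz: float = 3.0
    rr_amp: float = 1.0
    theta_rel_power: float = 0.3
    rr_beta_power_ratio: float = 10.0
    coupling: CouplingSpec = field(default_factory=CouplingSpec)
    pac_depth: float = 0.8
    pac_fast_hz: float = 30.0
    pac_amp: float = 0.3
    pac_preferred_phase: float = 0.0
    burst_rate_hz: float = 0.2
    burst_len_s: float = 2.5
    noise_sd: float = 0.3
    intrinsic_sd: float = 0.5
    spike_rates: tuple = (("MCL", 2.0), ("GCL", 1.0), ("CA1", 1.5), ("PFC", 1.5))
    n_units_per_group: int = 5
    spike_phase_kappa: float = 0.5
    # behavior session
    fps: float = 30.0
    session_s: float = 180.0
    zone_bias: float = 0.001
    step_sd_cm: float = 0.15
    likelihood_min: float = 0.9
    likelihood_drop_rate: float = 0.02
    test_side: str = "left"
    call_rate_hz: float = 0.4
    call_suppression: float = 0.25
    usv_trial_s: tuple = (90.0, 60.0, 60.0, 60.0)  # baseline, odor, post, break
    usv_factors: tuple | None = None  # per ascending concentration; default (1, 1, call_suppression)

    def trial_factors(self) -> tuple:
        """Call-rate multipliers during odor, per ascending concentration.

        Only the highest citral concentration suppresses calling by default.
        """
        return self.usv_factors if self.usv_factors is not None else (1.0, 1.0, self.call_suppression)
    seed: int = 0

    def validate(self) -> None:
        c = self.coupling
        for name, g in (
            ("gain_ob_ca1", c.gain_ob_ca1),
            ("gain_ob_pfc", c.gain_ob_pfc),
            ("gain_ca1_pfc", c.gain_ca1_pfc),
        ):
            if g < 0:
                raise ConfigError(f"{name} must be non-negative, got {g}")
            if g > 2.0:
                raise ConfigError(f"{name}={g} implies an unstable coupled system")
        if not 0 <= self.pac_depth <= 1:
            raise ConfigError(f"pac_depth must be in [0, 1], got {self.pac_depth}")
        if not 0 < self.mcl_index < self.n_ob_channels - 1:
            raise ConfigError("mcl_index must leave channels on both sides of the reversal")
        if not 2.0 <= self.rr_freq_hz <= 4.0:
            raise ConfigError(f"rr_freq_hz must lie in the RR band [2, 4], got {self.rr_freq_hz}")


@dataclass
class GroundTruth:
    """Everything needed to score recovery without re-simulating."""

    config: SyntheticConfig
    mcl_index: int = None
    rr_freq_hz: float = None
    pac_depth: float = None
    pac_fast_hz: float = None
    pac_preferred_phase: float = None
    coupling: CouplingSpec = None
    gate_duty: dict = field(default_factory=dict)
    unit_info: pd.DataFrame = None  # unit_id, group, channel, rate_hz, expected_rate_hz
    dwell_s: dict = field(default_factory=dict)
    n_excluded_frames: int = 0
    call_windows: list = field(default_factory=list)  # (t0, t1, role, trial, count)
    di_true: float = None

    def to_jsonable(self) -> dict:
        out = {
            "config": _config_to_dict(self.config),
            "mcl_index": self.mcl_index,
            "rr_freq_hz": self.rr_freq_hz,
            "pac_depth": self.pac_depth,
            "pac_fast_hz": self.pac_fast_hz,
            "pac_preferred_phase": self.pac_preferred_phase,
            "gate_duty": self.gate_duty,
            "dwell_s": self.dwell_s,
            "n_excluded_frames": self.n_excluded_frames,
            "call_windows": self.call_windows,
            "di_true": self.di_true,
        }
        if self.unit_info is not None:
            out["unit_info"] = self.unit_info.to_dict(orient="records")
        return out


def _config_to_dict(cfg: SyntheticConfig) -> dict:
    d = asdict(cfg)
    d["spike_rates"] = dict(cfg.spike_rates)
    return d


def _pink_noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """1/f-power shaped Gaussian noise with standard deviation ``sd``."""
    if sd == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    return sd * x / x.std()


def _narrowband(rng: np.random.Generator, n: int, fs: float, lo: float, hi: float) -> np.ndarray:
    """Unit-variance noise-driven narrowband oscillation."""
    x = bandpass(rng.standard_normal(n), fs, FilterSpec(lo, hi, order=2))
    return x / x.std()


def _burst_gate(
    rng: np.random.Generator, n: int, fs: float, rate_hz: float, len_s: float
) -> np.ndarray:
    """Alternating ON/OFF gate with exponential epoch lengths, smoothed.

    Mean ON duration is ``len_s``; OFF durations are exponential with mean
    ``max(1/rate_hz - len_s, 0.1)`` so bursts recur at roughly ``rate_hz``.
    ``rate_hz = 0`` disables gating (gate identically 1).
    """
    if rate_hz <= 0:
        return np.ones(n)
    off_mean = max(1.0 / rate_hz - len_s, 0.1)
    gate = np.zeros(n)
    t = int(rng.exponential(off_mean) * fs)  # start in an OFF epoch of random length
    on = True
    while t < n:
        dur = int(max(1, rng.exponential(len_s if on else off_mean) * fs))
        if on:
            gate[t : t + dur] = 1.0
        t += dur
        on = not on
    # 100 ms raised-cosine smoothing to avoid step transients
    win = sps.windows.hann(max(3, int(0.1 * fs)))
    gate = np.convolve(gate, win / win.sum(), mode="same")
    return gate


def _shift(x: np.ndarray, d: int) -> np.ndarray:
    """Causal delay by ``d`` samples (circular; d << n)."""
    return np.roll(x, d)


def generate_recording(cfg: SyntheticConfig) -> tuple[Recording, GroundTruth]:
    """Simulate one triple-area recording with known ground truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs
    n = int(round(cfg.duration_s * fs))

    # OB oscillatory components
    rr = cfg.rr_amp * _narrowband(rng, n, fs, cfg.rr_freq_hz - 0.4, cfg.rr_freq_hz + 0.4)
    theta = cfg.rr_amp * np.sqrt(cfg.theta_rel_power) * _narrowband(rng, n, fs, 6.0, 10.0)
    beta = cfg.rr_amp / np.sqrt(cfg.rr_beta_power_ratio) * _narrowband(rng, n, fs, 15.0, 25.0)
    rr_phase = analytic_signal(rr).phase
    ob_composite = rr + theta + beta

    samples = np.empty((cfg.n_ob_channels + 2, n))
    channels = []
    for i in range(cfg.n_ob_channels):
        sign = 1.0 if i <= cfg.mcl_index else -1.0
        samples[i] = sign * rr + theta + beta + _pink_noise(rng, n, cfg.noise_sd)
        channels.append(ChannelMeta(area="OB", depth_um=400.0 + 50.0 * i, index=i))

    cpl = cfg.coupling
    sensor_sd = max(0.05, 0.3 * cfg.noise_sd)

    def fast_component(rng_local):
        psi = rng_local.uniform(0, 2 * np.pi)
        env = 1.0 + cfg.pac_depth * np.cos(rr_phase - cfg.pac_preferred_phase)
        t = np.arange(n) / fs
        return cfg.pac_amp * env * np.cos(2 * np.pi * cfg.pac_fast_hz * t + psi)

    ca1_core = (
        cpl.gain_ob_ca1 * _shift(ob_composite, cpl.delay_ob_ca1)
        + _pink_noise(rng, n, cfg.intrinsic_sd)
    )
    gate_ca1 = _burst_gate(rng, n, fs, cfg.burst_rate_hz, cfg.burst_len_s)
    samples[cfg.n_ob_channels] = gate_ca1 * (ca1_core + fast_component(rng)) + _pink_noise(
        rng, n, sensor_sd
    )
    channels.append(ChannelMeta(area="CA1", depth_um=1600.0, index=cfg.n_ob_channels))

    pfc_core = (
        cpl.gain_ob_pfc * _shift(ob_composite, cpl.delay_ob_pfc)
        + cpl.gain_ca1_pfc * _shift(ca1_core, cpl.delay_ca1_pfc)
        + _pink_noise(rng, n, cfg.intrinsic_sd)
    )
    gate_pfc = _burst_gate(rng, n, fs, cfg.burst_rate_hz, cfg.burst_len_s)
    samples[cfg.n_ob_channels + 1] = gate_pfc * (pfc_core + fast_component(rng)) + _pink_noise(
        rng, n, sensor_sd
    )
    channels.append(ChannelMeta(area="PFC", depth_um=1900.0, index=cfg.n_ob_channels + 1))

    rec = Recording(samples=samples, fs=fs, channels=channels)
    gt = GroundTruth(
        config=cfg,
        mcl_index=cfg.mcl_index,
        rr_freq_hz=cfg.rr_freq_hz,
        pac_depth=cfg.pac_depth,
        pac_fast_hz=cfg.pac_fast_hz,
        pac_preferred_phase=cfg.pac_preferred_phase,
        coupling=cpl,
        gate_duty={"CA1": float(gate_ca1.mean()), "PFC": float(gate_pfc.mean())},
    )
    return rec, gt


def generate_spike_trains(
    cfg: SyntheticConfig, rec: Recording, gt: GroundTruth | None = None
) -> SpikeTable:
    """Inhomogeneous Poisson spikes phase-locked to the local RR.

    OB units are placed so layer assignment is recoverable: MCL units on
    channels ``mcl_index - 1 .. mcl_index + 1``, GCL units on channels
    deeper than ``mcl_index + 3``. Rates are modulated as
    ``lambda(t) = rate * (1 + kappa * cos(phi_RR(t) - phi_unit))``; the time
    average equals the configured rate. CA1/PFC unit rates are additionally
    gated by the area's burst gate (recorded in the ground truth as the
    expected realized rate).
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    duration = rec.duration
    fs = rec.fs
    rates = dict(cfg.spike_rates)

    # recover the RR phase from the shallowest OB channel (generator-side
    # bookkeeping; noise-free w.r.t. unit placement)
    ob0 = rec.get_channel(rec.channel_indices("OB")[0])
    phase = analytic_signal(
        bandpass(ob0, fs, FilterSpec(cfg.rr_freq_hz - 0.5, cfg.rr_freq_hz + 0.5))
    ).phase

    mcl = cfg.mcl_index
    placements: list[tuple[str, int]] = []
    mcl_chans = [mcl - 1, mcl, mcl + 1]
    gcl_chans = list(range(mcl + 4, cfg.n_ob_channels))
    for u in range(cfg.n_units_per_group):
        placements.append(("MCL", mcl_chans[u % len(mcl_chans)]))
    for u in range(cfg.n_units_per_group):
        placements.append(("GCL", gcl_chans[u % len(gcl_chans)]))
    ca1_ch = rec.channel_indices("CA1")[0]
    pfc_ch = rec.channel_indices("PFC")[0]
    for u in range(cfg.n_units_per_group):
        placements.append(("CA1", rec.channels[ca1_ch].index))
        placements.append(("PFC", rec.channels[pfc_ch].index))

    rows = []
    info = []
    kappa = cfg.spike_phase_kappa
    for unit_id, (group, channel) in enumerate(placements):
        lam = rates[group]
        expected = lam
        if lam <= 0:
            info.append(
                {"unit_id": unit_id, "group": group, "channel": channel,
                 "rate_hz": lam, "expected_rate_hz": 0.0}
            )
            continue
        lam_max = lam * (1 + kappa)
        n_cand = rng.poisson(lam_max * duration)
        t_cand = np.sort(rng.uniform(0, duration, n_cand))
        idx = np.minimum((t_cand * fs).astype(np.intp), len(phase) - 1)
        phi_u = rng.uniform(0, 2 * np.pi)
        accept_p = lam * (1 + kappa * np.cos(phase[idx] - phi_u)) / lam_max
        keep = rng.uniform(size=n_cand) < accept_p
        t_spk = t_cand[keep]
        for t in t_spk:
            rows.append({"unit_id": unit_id, "channel": channel, "t": float(t)})
        info.append(
            {"unit_id": unit_id, "group": group, "channel": channel,
             "rate_hz": lam, "expected_rate_hz": expected}
        )
    df = pd.DataFrame(rows, columns=["unit_id", "channel", "t"])
    table = SpikeTable(df=df)
    if gt is not None:
        gt.unit_info = pd.DataFrame(info)
    return table


def generate_behavior_session(cfg: SyntheticConfig) -> tuple[TrackTable, CallTable, GroundTruth]:
    """Simulate one odor-place tracking session and one USV call session.

    The track is a reflected random walk over the arena with a constant
    drift ``zone_bias`` (cm/frame) toward the test side; realized per-zone
    dwell times over the frames that pass the likelihood gate are recorded
    in the ground truth with the same zone mapping the analysis uses, so
    occupancy recovery is frame-exact. Calls are a piecewise-homogeneous
    Poisson train following the citral session template (baseline / odor /
    post / break, three ascending concentrations) with the configured
    suppression factor per trial.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    geom = ArenaGeometry()
    n_frames = int(round(cfg.session_s * cfg.fps))
    drift = cfg.zone_bias if cfg.test_side == "right" else -cfg.zone_bias
    steps = drift + cfg.step_sd_cm * rng.standard_normal(n_frames - 1)
    x = np.empty(n_frames)
    x[0] = geom.length_cm / 2
    for i in range(1, n_frames):  # reflecting walls
        xi = x[i - 1] + steps[i - 1]
        while xi < 0 or xi > geom.length_cm:
            xi = -xi if xi < 0 else 2 * geom.length_cm - xi
        x[i] = xi
    y = np.clip(geom.zone_cm / 2 + 0.5 * rng.standard_normal(n_frames), 0, geom.zone_cm)
    likelihood = 1.0 - 0.02 * rng.random(n_frames)
    dropped = rng.random(n_frames) < cfg.likelihood_drop_rate
    likelihood[dropped] = 0.5 * rng.random(int(dropped.sum()))
    track = TrackTable(
        df=pd.DataFrame(
            {
                "frame": np.arange(n_frames),
                "x_cm": x,
                "y_cm": y,
                "likelihood": likelihood,
            }
        ),
        fps=cfg.fps,
    )
    keep = likelihood >= cfg.likelihood_min
    labels = zone_labels(x[keep], geom, cfg.test_side)
    dwell = {
        z: float((labels == z).sum() / cfg.fps)
        for z in (ZONE_TEST, ZONE_CONTROL, ZONE_NEUTRAL)
    }
    denom = dwell[ZONE_TEST] + dwell[ZONE_CONTROL]
    di_true = (dwell[ZONE_TEST] - dwell[ZONE_CONTROL]) / denom if denom > 0 else np.nan

    # USV call train over the citral session template
    base_s, odor_s, post_s, break_s = cfg.usv_trial_s
    windows = []  # (t0, t1, rate)
    t = 0.0
    for trial, factor in enumerate(cfg.trial_factors()):
        windows.append((t, t + base_s, cfg.call_rate_hz, "baseline", trial))
        t += base_s
        windows.append((t, t + odor_s, cfg.call_rate_hz * factor, "odor", trial))
        t += odor_s
        windows.append((t, t + post_s, cfg.call_rate_hz, "post", trial))
        t += post_s + break_s
    onsets = []
    call_windows = []
    for t0, t1, rate, role, trial in windows:
        k = rng.poisson(rate * (t1 - t0))
        ts = np.sort(rng.uniform(t0, t1, k))
        onsets.append(ts)
        call_windows.append((t0, t1, role, trial, int(k)))
    t_on = np.concatenate(onsets) if onsets else np.array([])
    t_on.sort()
    dur = 0.03 + 0.07 * rng.random(len(t_on))
    peak = rng.uniform(40.0, 90.0, len(t_on))
    calls = CallTable(
        df=pd.DataFrame({"t_on": t_on, "t_off": t_on + dur, "peak_freq_khz": peak})
    )
    gt = GroundTruth(
        config=cfg,
        dwell_s=dwell,
        n_excluded_frames=int((~keep).sum()),
        call_windows=call_windows,
        di_true=float(di_true),
    )
    return track, calls, gt


def event_table_for_session(cfg: SyntheticConfig) -> pd.DataFrame:
    """Odor on/off events matching the generated call-session template."""
    base_s, odor_s, post_s, break_s = cfg.usv_trial_s
    rows = []
    t = 0.0
    for trial in range(len(cfg.trial_factors())):
        rows.append({"kind": "odor_on", "t": t + base_s, "label": f"citral_{trial}"})
        rows.append({"kind": "odor_off", "t": t + base_s + odor_s, "label": f"citral_{trial}"})
        t += base_s + odor_s + post_s + break_s
    return pd.DataFrame(rows, columns=["kind", "t", "label"])
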