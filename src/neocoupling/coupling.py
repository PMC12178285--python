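"""Inter-areal interaction measures.

Three measures quantify how the olfactory bulb (OB) engages the
hippocampal-prefrontal (CA1/PFC) network:

* **Frequency-resolved amplitude correlation** -- Pearson correlation of
  Hilbert envelopes in 2 Hz bands from 1 to 30 Hz; non-directed.
* **Generalized partial directed coherence (gPDC)** -- a frequency-domain,
  noise-variance-normalized Granger measure derived from multivariate
  autoregressive (MVAR) models; directed. For the model
  ``x(t) = sum_r A_r x(t-r) + e(t)`` with residual variances
  ``sigma_k^2``, define ``Abar(f) = I - sum_r A_r exp(-2i*pi*f*r/fs)``; then

  ``gpdc[i<-j](f) = (|Abar_ij(f)| / sigma_i) / sqrt(sum_k |Abar_kj(f)|^2 / sigma_k^2)``

  so that the squared values sum to 1 over targets ``i`` for every source
  ``j`` and frequency.
* **Phase-amplitude coupling (PAC)** -- modulation of fast (12-50 Hz) CA1/PFC
  amplitude by the slow (1-4 Hz) OB phase, quantified per
  (phase-frequency, amplitude-frequency) cell by the Tort modulation index
  (KL divergence of the phase-binned mean-amplitude profile from uniform,
  normalized by ``log n_bins``), with a z-scored comodulogram and a
  surrogate-calibrated summary over RR phase x 13-50 Hz amplitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats as ss

from .errors import (
    FitError,
    LengthError,
    ParameterError,
    QualityError,
    UnstableModelWarning,
)
from .preprocess import FilterSpec, analytic_signal, bandpass, edge_slice, wavelet_denoise
from .spectral import BandDefinition

#: two-sided standard-normal critical value at alpha = 0.05
PAC_Z_CRITICAL = float(ss.norm.ppf(1 - 0.05 / 2))


# ---------------------------------------------------------------------------
# amplitude correlation


@dataclass
class AmplitudeCorrelationResult:
    """Pearson r between band-limited envelopes per 2 Hz bin (one area pair)."""

    bin_centers: np.ndarray
    r: np.ndarray


def amplitude_correlation_bins(
    low: float = 1.0, high: float = 30.0, width: float = 2.0
) -> list[tuple[float, float]]:
    """Half-open 2 Hz bins with lower edges 1, 3, ..., 29 Hz; last bin
    truncated at 30 Hz."""
    edges = np.arange(low, high, width)
    return [(float(e), float(min(e + width, high))) for e in edges]


def amplitude_correlation(x, y, fs: float) -> AmplitudeCorrelationResult:
    """Frequency-resolved envelope correlation between two channels.

    Both signals are bandpass filtered per bin (zero-phase Butterworth,
    order 3), Hilbert transformed, and the Pearson correlation of the two
    envelopes is computed with edge-contaminated samples excluded.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ParameterError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.shape[-1] < 10 * fs:
        raise LengthError("amplitude correlation requires at least 10 s of data")
    bins = amplitude_correlation_bins()
    centers = np.array([(lo + hi) / 2 for lo, hi in bins])
    sl = edge_slice(x.shape[-1], fs)
    r = np.empty(len(bins))
    for b, (lo, hi) in enumerate(bins):
        spec = FilterSpec(lo, hi)
        ex = analytic_signal(bandpass(x, fs, spec)).envelope[sl]
        ey = analytic_signal(bandpass(y, fs, spec)).envelope[sl]
        r[b] = np.corrcoef(ex, ey)[0, 1]
    return AmplitudeCorrelationResult(bin_centers=centers, r=r)


# ---------------------------------------------------------------------------
# MVAR / gPDC


@dataclass
class MVARModel:
    """Least-squares MVAR fit: ``x(t) = sum_r coeffs[r-1] x(t-r) + e(t)``."""

    order: int
    coeffs: np.ndarray  # [p, k, k]
    noise_cov: np.ndarray  # [k, k]
    fs_model: float
    stable: bool = True

    @property
    def k(self) -> int:
        return self.coeffs.shape[1]


def _companion_spectral_radius(coeffs: np.ndarray) -> float:
    p, k, _ = coeffs.shape
    comp = np.zeros((k * p, k * p))
    comp[:k, :] = np.concatenate([coeffs[r] for r in range(p)], axis=1)
    if p > 1:
        comp[k:, :-k] = np.eye(k * (p - 1))
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


def fit_mvar(X, p: int, fs_model: float = 1.0, check_sample_size: bool = True) -> MVARModel:
    """Ordinary-least-squares MVAR fit of order ``p`` on a [k x n] segment.

    The regression is deterministic; models whose companion matrix has
    spectral radius >= 1 are flagged unstable (with a warning) but returned.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ParameterError("X must be [k x n]")
    k, n = X.shape
    if p < 1:
        raise ParameterError(f"order must be >= 1, got {p}")
    if check_sample_size and n < 10 * k * p:
        raise LengthError(
            f"segment length {n} < 10 x k x p = {10 * k * p}; too short for a "
            f"reliable order-{p} fit on {k} channels"
        )
    n_obs = n - p
    if n_obs <= k * p:
        raise LengthError(f"only {n_obs} observations for {k * p} regressors")
    # design matrix of lagged values: predict X[:, p:] from lags 1..p
    Y = X[:, p:].T  # [n_obs, k]
    Z = np.concatenate([X[:, p - r : n - r].T for r in range(1, p + 1)], axis=1)
    beta, _, rank, _ = np.linalg.lstsq(Z, Y, rcond=None)
    if rank < k * p:
        raise FitError(f"rank-deficient regression (rank {rank} < {k * p})")
    coeffs = np.stack(
        [beta[r * k : (r + 1) * k, :].T for r in range(p)], axis=0
    )  # [p, k, k], coeffs[r][i, j]: lag r+1 influence of channel j on channel i
    resid = Y - Z @ beta
    noise_cov = resid.T @ resid / (n_obs - k * p)
    stable = _companion_spectral_radius(coeffs) < 1.0
    if not stable:
        warnings.warn("fitted MVAR model is unstable", UnstableModelWarning)
    return MVARModel(order=p, coeffs=coeffs, noise_cov=noise_cov, fs_model=fs_model, stable=stable)


def mvar_aic(model: MVARModel, n_obs: int) -> float:
    """Akaike information criterion for an MVAR fit."""
    sign, logdet = np.linalg.slogdet(model.noise_cov)
    if sign <= 0:
        return np.inf
    return float(logdet + 2.0 * model.k**2 * model.order / n_obs)


@dataclass
class GPDCResult:
    """gPDC spectra: ``pi[f, i, j]`` is the directed influence of source j on
    target i at ``freqs[f]``, in [0, 1]."""

    freqs: np.ndarray
    pi: np.ndarray  # [n_freqs, k, k]
    n_segments: int = 1
    n_dropped: int = 0

    def direction(self, target: int, source: int) -> np.ndarray:
        return self.pi[:, target, source]

    def band_mean(self, band: BandDefinition, target: int, source: int) -> float:
        mask = (self.freqs >= band.low_hz) & (self.freqs < band.high_hz)
        if not mask.any():
            raise ParameterError(f"no gPDC frequencies inside band {band.name}")
        return float(self.pi[mask, target, source].mean())


def _abar(model: MVARModel, freqs: np.ndarray) -> np.ndarray:
    """``Abar(f) = I - sum_r A_r exp(-2i*pi*f*r/fs_model)`` for all freqs."""
    p, k, _ = model.coeffs.shape
    r = np.arange(1, p + 1)
    phase = np.exp(-2j * np.pi * np.outer(freqs, r) / model.fs_model)  # [nf, p]
    acc = np.tensordot(phase, model.coeffs, axes=(1, 0))  # [nf, k, k]
    return np.eye(k)[None, :, :] - acc


def gpdc_spectrum(model: MVARModel, freqs) -> GPDCResult:
    """Generalized partial directed coherence of a fitted MVAR model.

    Columns are normalized so that ``sum_i pi[f, i, j]**2 == 1`` for every
    source ``j`` and frequency.
    """
    freqs = np.asarray(freqs, dtype=np.float64)
    sigma2 = np.diag(model.noise_cov).copy()
    if np.any(sigma2 <= 0):
        raise ParameterError("noise covariance has non-positive diagonal entries")
    A = _abar(model, freqs)  # [nf, k, k]
    w = np.abs(A) / np.sqrt(sigma2)[None, :, None]  # |Abar_ij| / sigma_i
    denom = np.sqrt(np.sum(w**2, axis=1, keepdims=True))  # per source column
    return GPDCResult(freqs=freqs, pi=w / denom)


def select_mvar_order(
    segments: list[np.ndarray],
    fs_model: float,
    p_range=(2, 20),
    max_calibration: int = 10,
) -> int:
    """Pick the MVAR order by AIC on a calibration subset of segments.

    The searched range is clipped so the documented sample-size requirement
    ``n >= 10 * k * p`` holds for the given segment length.
    """
    if not segments:
        raise ParameterError("no segments to calibrate the model order on")
    k, n = segments[0].shape
    p_max = min(p_range[1], n // (10 * k))
    p_min = min(p_range[0], p_max)
    if p_max < 1:
        raise LengthError(f"segments of {n} samples cannot support any MVAR order")
    calib = segments[: min(max_calibration, len(segments))]
    scores = {}
    for p in range(p_min, p_max + 1):
        vals = []
        for seg in calib:
            try:
                m = fit_mvar(seg, p, fs_model=fs_model, check_sample_size=False)
            except (FitError, LengthError):
                continue
            vals.append(mvar_aic(m, seg.shape[1] - p))
        if vals:
            scores[p] = float(np.median(vals))
    if not scores:
        raise FitError("order selection failed on every calibration segment")
    return min(scores, key=scores.get)


def gpdc_pipeline(
    rec,
    areas=("OB", "CA1", "PFC"),
    channels: dict[str, int] | None = None,
    segment_s: float = 1.0,
    fs_model: float = 100.0,
    order: int | str = 2,
    freqs=None,
    min_segments: int = 30,
) -> GPDCResult:
    """Segment-averaged gPDC between one LFP channel per area.

    Each ``segment_s`` segment is wavelet-denoised per channel, decimated to
    ``fs_model`` (with anti-alias filtering), fit with an OLS MVAR model, and
    converted to gPDC; unstable fits are dropped and counted. The returned
    ``pi`` is the mean gPDC magnitude over retained segments, with areas
    ordered as in ``areas`` (``pi[:, i, j]`` = influence of ``areas[j]`` on
    ``areas[i]``).

    ``order`` defaults to 2: on 1 s segments decimated to 100 Hz, higher
    orders (including the AIC pick on these data) leave more coefficient
    noise per fit, which inflates spurious directed influence *out of*
    strongly autocorrelated narrowband sources; order-2 null simulations are
    directionally symmetric while still resolving the coupling delays of
    interest. Pass ``order="aic"`` (or None) for AIC selection on a
    calibration subset.
    """
    if channels is None:
        channels = {}
        for area in areas:
            idx = rec.channel_indices(area)
            if not idx:
                raise ParameterError(f"recording has no {area} channels")
            channels[area] = idx[0]
    X = np.stack([rec.get_channel(channels[a]) for a in areas])
    k = X.shape[0]
    seg_len = int(round(segment_s * rec.fs))
    n_seg = X.shape[1] // seg_len
    if n_seg < min_segments:
        raise LengthError(f"only {n_seg} segments of {segment_s} s; need >= {min_segments}")
    q = int(round(rec.fs / fs_model))
    if q < 1 or abs(rec.fs / q - fs_model) > 1e-9:
        raise ParameterError(f"fs {rec.fs} is not an integer multiple of fs_model {fs_model}")
    if freqs is None:
        freqs = np.arange(1.0, fs_model / 2, 1.0)
    else:
        freqs = np.asarray(freqs, dtype=np.float64)

    segments = []
    for s in range(n_seg):
        seg = X[:, s * seg_len : (s + 1) * seg_len]
        den = np.stack([wavelet_denoise(seg[c]) for c in range(k)])
        if q > 1:
            den = sps.decimate(den, q, axis=-1, zero_phase=True)
        segments.append(den)

    if order is None or order == "aic":
        order = select_mvar_order(segments, fs_model)

    acc = np.zeros((len(freqs), k, k))
    kept = 0
    dropped = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UnstableModelWarning)
        for seg in segments:
            try:
                model = fit_mvar(seg, order, fs_model=fs_model, check_sample_size=False)
            except FitError:
                dropped += 1
                continue
            if not model.stable:
                dropped += 1
                continue
            acc += gpdc_spectrum(model, freqs).pi
            kept += 1
    if dropped > len(segments) / 2:
        raise QualityError(
            f"{dropped}/{len(segments)} segments produced unstable or failed fits"
        )
    return GPDCResult(freqs=freqs, pi=acc / kept, n_segments=kept, n_dropped=dropped)


# ---------------------------------------------------------------------------
# phase-amplitude coupling


@dataclass
class Comodulogram:
    """PAC matrix over (slow phase frequency) x (fast amplitude frequency).

    ``raw`` holds the Tort modulation index per cell; ``z`` is the matrix
    z-scored across all entries (mean 0, SD 1) unless surrogate z-scoring was
    requested. ``profiles[p, a]`` is the mean amplitude per phase bin for
    cell (p, a). ``summary_raw``/``summary_z`` carry the surrogate-calibrated
    RR x 13-50 Hz summary used by :func:`pac_summary`.
    """

    phase_freqs: np.ndarray
    amp_freqs: np.ndarray
    raw: np.ndarray
    z: np.ndarray
    n_phase_bins: int
    profiles: np.ndarray = field(default=None, repr=False)
    summary_raw: float = np.nan
    summary_z: float = np.nan
    summary_surrogates: np.ndarray = field(default=None, repr=False)


@dataclass
class PACSummary:
    """Surrogate-calibrated z of RR-phase to 13-50 Hz amplitude coupling."""

    z_mean: float
    significant: bool
    threshold: float = PAC_Z_CRITICAL


def _tort_mi(bin_sums: np.ndarray, bin_counts: np.ndarray) -> np.ndarray:
    """Tort modulation index from per-phase-bin amplitude sums and counts.

    ``bin_sums`` may carry extra leading axes; the last axis is phase bins.
    MI = (log N - H(P)) / log N where P is the normalized mean-amplitude
    profile over the N phase bins.
    """
    means = bin_sums / bin_counts
    total = means.sum(axis=-1, keepdims=True)
    p = means / total
    n_bins = bin_sums.shape[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    entropy = -plogp.sum(axis=-1)
    return (np.log(n_bins) - entropy) / np.log(n_bins)


def pac_comodulogram(
    slow,
    fast,
    fs: float,
    phase_freqs=None,
    amp_freqs=None,
    n_phase_bins: int = 20,
    phase_halfwidth: float = 0.5,
    amp_halfwidth: float = 5.0,
    n_surrogates: int = 200,
    subsample_hz: float = 50.0,
    zscore: str = "matrix",
    summary_phase_band: tuple[float, float] = (2.0, 4.0),
    summary_amp_band: tuple[float, float] = (13.0, 50.0),
    random_state=None,
) -> Comodulogram:
    """Phase-amplitude comodulogram between a slow and a fast channel.

    For each slow center (1-4 Hz, 1 Hz steps) the phase of ``slow`` and for
    each fast center (12-50 Hz, 2 Hz steps) the envelope of ``fast`` are
    extracted (zero-phase Butterworth + Hilbert), edge-cropped, and
    subsampled to ``subsample_hz`` before the envelope is averaged within
    ``n_phase_bins`` phase bins; coupling strength per cell is the Tort MI of
    that profile. The matrix ``z`` is z-scored across entries
    (``zscore="matrix"``) or against per-cell circular-shift surrogates
    (``zscore="surrogate"``). The summary statistic (mean raw MI over
    ``summary_phase_band`` rows x ``summary_amp_band`` columns) is always
    standardized against the same ``n_surrogates`` circular shifts; this
    calibrated z is what :func:`pac_summary` thresholds.
    """
    slow = np.asarray(slow, dtype=np.float64)
    fast = np.asarray(fast, dtype=np.float64)
    if slow.shape != fast.shape:
        raise ParameterError("slow and fast channels must have equal length")
    if slow.shape[-1] < 60 * fs:
        raise LengthError("PAC requires at least 60 s of data")
    if zscore not in ("matrix", "surrogate"):
        raise ParameterError(f"unknown zscore mode {zscore!r}")
    if phase_freqs is None:
        phase_freqs = np.arange(1.0, 4.0 + 0.5, 1.0)
    else:
        phase_freqs = np.asarray(phase_freqs, dtype=np.float64)
    if amp_freqs is None:
        amp_freqs = np.arange(12.0, 50.0 + 1.0, 2.0)
    else:
        amp_freqs = np.asarray(amp_freqs, dtype=np.float64)
    rng = np.random.default_rng(random_state)

    n = slow.shape[-1]
    sl = edge_slice(n, fs)
    step = max(1, int(round(fs / subsample_hz)))
    n_p, n_a = len(phase_freqs), len(amp_freqs)

    # phase-bin index series per phase frequency
    bin_idx = []
    for pf in phase_freqs:
        ph = analytic_signal(
            bandpass(slow, fs, FilterSpec(pf - phase_halfwidth, pf + phase_halfwidth))
        ).phase[sl][::step]
        idx = np.floor((ph + np.pi) / (2 * np.pi) * n_phase_bins).astype(np.intp)
        bin_idx.append(np.clip(idx, 0, n_phase_bins - 1))
    m = bin_idx[0].shape[0]

    # envelope series per amplitude frequency
    envs = np.empty((n_a, m))
    for a, af in enumerate(amp_freqs):
        envs[a] = analytic_signal(
            bandpass(fast, fs, FilterSpec(af - amp_halfwidth, af + amp_halfwidth))
        ).envelope[sl][::step]

    # one-hot phase-bin indicators per phase row: B[p] is [n_bins x m]
    counts = np.empty((n_p, n_phase_bins))
    indicators = np.zeros((n_p, n_phase_bins, m))
    for p in range(n_p):
        indicators[p, bin_idx[p], np.arange(m)] = 1.0
        counts[p] = indicators[p].sum(axis=1)
    if np.any(counts == 0):
        raise QualityError("empty phase bins; data too short for the requested binning")

    # observed MI and phase-bin profiles
    raw = np.empty((n_p, n_a))
    profiles = np.empty((n_p, n_a, n_phase_bins))
    for p in range(n_p):
        sums = indicators[p] @ envs.T  # [n_bins, n_a]
        profiles[p] = (sums / counts[p][:, None]).T
        raw[p] = _tort_mi(sums.T, counts[p][None, :])

    # circular-shift surrogates of the envelopes (shared across cells)
    min_shift = max(1, int(round(subsample_hz)))  # at least ~1 s of shift
    shifts = rng.integers(min_shift, m - min_shift, size=n_surrogates)
    surr_mi = np.empty((n_surrogates, n_p, n_a))
    gather = (np.arange(m)[None, :] - shifts[:, None]) % m  # [n_surr, m]
    for a in range(n_a):
        shifted = envs[a][gather]  # [n_surr, m]
        for p in range(n_p):
            sums = shifted @ indicators[p].T  # [n_surr, n_bins]
            surr_mi[:, p, a] = _tort_mi(sums, counts[p][None, :])

    if zscore == "matrix":
        sd = raw.std()
        z = (raw - raw.mean()) / sd if sd > 0 else np.zeros_like(raw)
    else:
        mu = surr_mi.mean(axis=0)
        sd = surr_mi.std(axis=0, ddof=1)
        z = (raw - mu) / np.where(sd > 0, sd, 1.0)

    p_mask = (phase_freqs >= summary_phase_band[0]) & (phase_freqs <= summary_phase_band[1])
    a_mask = (amp_freqs >= summary_amp_band[0]) & (amp_freqs <= summary_amp_band[1])
    obs = raw[np.ix_(p_mask, a_mask)].mean()
    surr = surr_mi[:, p_mask][:, :, a_mask].mean(axis=(1, 2))
    s_sd = surr.std(ddof=1)
    summary_z = (obs - surr.mean()) / s_sd if s_sd > 0 else 0.0

    return Comodulogram(
        phase_freqs=phase_freqs,
        amp_freqs=amp_freqs,
        raw=raw,
        z=z,
        n_phase_bins=n_phase_bins,
        profiles=profiles,
        summary_raw=float(obs),
        summary_z=float(summary_z),
        summary_surrogates=surr,
    )


def pac_summary(c: Comodulogram, threshold: float = PAC_Z_CRITICAL) -> PACSummary:
    """Significance call for RR-phase to 13-50 Hz amplitude coupling.

    ``z_mean`` is the surrogate-calibrated z of the mean coupling strength
    over the RR-phase rows and 13-50 Hz amplitude columns; coupling is
    significant when it strictly exceeds ``threshold`` (default 1.96, the
    two-sided standard-normal critical value at alpha = 0.05).
    """
    z_mean = float(c.summary_z)
    return PACSummary(z_mean=z_mean, significant=bool(z_mean > threshold), threshold=threshold)
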