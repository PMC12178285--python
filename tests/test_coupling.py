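"""Amplitude correlation, MVAR/gPDC and PAC behavior on constructed signals."""


import numpy as np
import pytest

from neocoupling.coupling import (
    PAC_Z_CRITICAL,
    Comodulogram,
    MVARModel,
    amplitude_correlation,
    fit_mvar,
    gpdc_pipeline,
    gpdc_spectrum,
    pac_comodulogram,
    pac_summary,
)
from neocoupling.errors import LengthError, ParameterError, UnstableModelWarning
from neocoupling.preprocess import FilterSpec, bandpass
from neocoupling.spectral import RR_BAND
from neocoupling.synthetic_data import CouplingSpec, SyntheticConfig, generate_recording

FS = 1000.0


def simulate_var(coeffs, n, rng, noise_sd=1.0):
    """Direct time-domain VAR simulation (independent of fit_mvar)."""
    coeffs = np.asarray(coeffs, dtype=float)
    p, k, _ = coeffs.shape
    x = np.zeros((k, n))
    e = noise_sd * rng.standard_normal((k, n))
    for t in range(p, n):
        acc = e[:, t].copy()
        for r in range(p):
            acc += coeffs[r] @ x[:, t - r - 1]
        x[:, t] = acc
    return x


def gpdc_bruteforce(coeffs, noise_cov, fs_model, freqs):
    """Element-wise loop evaluation of the gPDC definition (oracle)."""
    coeffs = np.asarray(coeffs, dtype=float)
    p, k, _ = coeffs.shape
    sigma2 = np.diag(noise_cov)
    out = np.empty((len(freqs), k, k))
    for fi, f in enumerate(freqs):
        abar = np.eye(k, dtype=complex)
        for r in range(1, p + 1):
            abar -= coeffs[r - 1] * np.exp(-2j * np.pi * f * r / fs_model)
        for j in range(k):
            denom = np.sqrt(sum(abs(abar[kk, j]) ** 2 / sigma2[kk] for kk in range(k)))
            for i in range(k):
                out[fi, i, j] = (abs(abar[i, j]) / np.sqrt(sigma2[i])) / denom
    return out


def random_stable_var2(rng, k=3):
    """Random stable VAR(2) system with positive-definite noise covariance."""
    while True:
        coeffs = 0.35 * rng.standard_normal((2, k, k))
        m = MVARModel(order=2, coeffs=coeffs, noise_cov=np.eye(k), fs_model=100.0)
        comp = np.zeros((2 * k, 2 * k))
        comp[:k, :k], comp[:k, k:] = coeffs[0], coeffs[1]
        comp[k:, :k] = np.eye(k)
        if np.max(np.abs(np.linalg.eigvals(comp))) < 0.95:
            L = rng.standard_normal((k, k)) * 0.2 + np.eye(k)
            m.noise_cov = L @ L.T
            return m


class TestAmplitudeCorrelation:
    def test_identical_channels_correlate_perfectly(self, rng):
        x = rng.standard_normal(int(20 * FS))
        res = amplitude_correlation(x, x, FS)
        assert np.allclose(res.r, 1.0)

    def test_independent_noise_uncorrelated(self, rng):
        # 2 Hz-wide envelopes decorrelate over ~0.5 s, so 120 s gives roughly
        # 240 effective samples per bin: null SD ~ 0.065, bound at ~3 SD
        x, y = rng.standard_normal((2, int(120 * FS)))
        res = amplitude_correlation(x, y, FS)
        assert np.all(np.abs(res.r) < 0.2)
        assert np.abs(res.r).mean() < 0.08

    def test_shared_slow_envelope_detected_in_matching_bin(self, rng):
        t = np.arange(0, 60, 1 / FS)
        env = 1.0 + 0.9 * np.clip(
            bandpass(rng.standard_normal(t.size), FS, FilterSpec(0.1, 0.5, order=2))
            / 0.4, -1, 1,
        )
        x = env * np.cos(2 * np.pi * 8 * t) + 0.05 * rng.standard_normal(t.size)
        y = env * np.cos(2 * np.pi * 8 * t + 1.0) + 0.05 * rng.standard_normal(t.size)
        res = amplitude_correlation(x, y, FS)
        bin_78 = int(np.flatnonzero(res.bin_centers == 8.0)[0])
        assert res.r[bin_78] > 0.9

    def test_symmetry(self, rng):
        x, y = rng.standard_normal((2, int(12 * FS)))
        a = amplitude_correlation(x, y, FS)
        b = amplitude_correlation(y, x, FS)
        assert np.allclose(a.r, b.r)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            amplitude_correlation(np.zeros(11000), np.zeros(12000), FS)


class TestFitMvar:
    A_TRUE = np.array([[[0.5, 0.0], [0.4, 0.5]]])

    def test_recovers_var1_coefficients(self, rng):
        x = simulate_var(self.A_TRUE, 100_000, rng)
        m = fit_mvar(x, 1)
        assert np.abs(m.coeffs - self.A_TRUE).max() < 0.02
        assert np.abs(np.diag(m.noise_cov) - 1.0).max() < 0.05
        assert m.stable

    def test_white_noise_gives_null_coefficients(self, rng):
        x = rng.standard_normal((2, 100_000))
        m = fit_mvar(x, 2)
        assert np.abs(m.coeffs).max() < 0.05

    def test_deterministic(self, rng):
        x = simulate_var(self.A_TRUE, 5000, rng)
        a, b = fit_mvar(x, 1), fit_mvar(x, 1)
        assert np.array_equal(a.coeffs, b.coeffs)

    def test_agrees_with_statsmodels_var(self, rng):
        """Independent cross-check against the statsmodels VAR estimator."""
        from statsmodels.tsa.api import VAR

        x = simulate_var(self.A_TRUE, 20_000, rng)
        ours = fit_mvar(x, 1)
        theirs = VAR(x.T).fit(maxlags=1, trend="n")
        assert np.allclose(ours.coeffs[0], theirs.coefs[0], atol=1e-3)

    def test_too_short_segment_rejected(self):
        with pytest.raises(LengthError):
            fit_mvar(np.zeros((3, 50)), 5)

    def test_unstable_model_flagged(self, rng):
        x = simulate_var(np.array([[[1.03]]]), 300, rng)  # explosive AR(1)
        with pytest.warns(UnstableModelWarning):
            m = fit_mvar(x, 1, check_sample_size=False)
        assert not m.stable


class TestGpdcSpectrum:
    def test_matches_bruteforce_oracle_on_random_systems(self, rng):
        freqs = np.arange(1.0, 49.0, 1.0)
        for _ in range(10):
            m = random_stable_var2(rng)
            ours = gpdc_spectrum(m, freqs).pi
            oracle = gpdc_bruteforce(m.coeffs, m.noise_cov, m.fs_model, freqs)
            assert np.abs(ours - oracle).max() < 1e-10

    def test_column_normalization(self, rng):
        m = random_stable_var2(rng)
        pi = gpdc_spectrum(m, np.arange(1.0, 49.0)).pi
        assert np.abs((pi**2).sum(axis=1) - 1.0).max() < 1e-6

    def test_diagonal_var_has_zero_cross_terms(self):
        coeffs = np.array([[[0.5, 0.0], [0.0, -0.3]]])
        m = MVARModel(order=1, coeffs=coeffs, noise_cov=np.eye(2), fs_model=100.0)
        pi = gpdc_spectrum(m, np.arange(1.0, 49.0)).pi
        off = pi[:, [0, 1], [1, 0]]
        assert np.allclose(off, 0.0)

    def test_unidirectional_var_is_directed(self):
        coeffs = np.array([[[0.5, 0.0], [0.4, 0.5]]])
        m = MVARModel(order=1, coeffs=coeffs, noise_cov=np.eye(2), fs_model=100.0)
        g = gpdc_spectrum(m, np.arange(1.0, 10.0))
        assert g.pi[:, 1, 0].min() > 0.3  # 1 -> 2 present at low freqs
        assert g.pi[:, 0, 1].max() < 0.05  # 2 -> 1 absent

    def test_singular_noise_diagonal_rejected(self):
        m = MVARModel(
            order=1,
            coeffs=np.zeros((1, 2, 2)),
            noise_cov=np.diag([1.0, 0.0]),
            fs_model=100.0,
        )
        with pytest.raises(ParameterError):
            gpdc_spectrum(m, [5.0])


class TestGpdcPipeline:
    def test_recovers_coupling_direction(self):
        cfg = SyntheticConfig(
            duration_s=120.0,
            seed=11,
            coupling=CouplingSpec(gain_ob_ca1=0.6, gain_ob_pfc=0.0, gain_ca1_pfc=0.0),
        )
        rec, _ = generate_recording(cfg)
        g = gpdc_pipeline(rec)
        assert g.band_mean(RR_BAND, 1, 0) > g.band_mean(RR_BAND, 0, 1)

    def test_null_coupling_is_symmetric(self):
        cfg = SyntheticConfig(
            duration_s=120.0,
            seed=12,
            pac_depth=0.0,
            coupling=CouplingSpec(gain_ob_ca1=0.0, gain_ob_pfc=0.0, gain_ca1_pfc=0.0),
        )
        rec, _ = generate_recording(cfg)
        g = gpdc_pipeline(rec)
        fw = g.band_mean(RR_BAND, 1, 0)
        rv = g.band_mean(RR_BAND, 0, 1)
        assert abs(fw - rv) < 0.08  # wider than the 20-seed band for one short run

    def test_too_few_segments_rejected(self):
        cfg = SyntheticConfig(duration_s=120.0, seed=1)
        rec, _ = generate_recording(cfg)
        with pytest.raises(LengthError):
            gpdc_pipeline(rec, segment_s=10.0)


def make_pac_pair(depth, seed, dur=60.0, slow_hz=3.0, fast_hz=30.0, phase0=0.0):
    """Slow narrowband rhythm + fast carrier with phase-locked envelope."""
    rng = np.random.default_rng(seed)
    t = np.arange(0, dur, 1 / FS)
    slow = bandpass(rng.standard_normal(t.size), FS, FilterSpec(slow_hz - 0.4, slow_hz + 0.4, 2))
    slow /= slow.std()
    from neocoupling.preprocess import analytic_signal

    phase = analytic_signal(slow).phase
    env = 1.0 + depth * np.cos(phase - phase0)
    fast = 0.3 * env * np.cos(2 * np.pi * fast_hz * t + rng.uniform(0, 2 * np.pi))
    fast = fast + 0.1 * rng.standard_normal(t.size)
    return slow, fast


class TestPac:
    def test_raw_peak_at_injected_cell(self):
        slow, fast = make_pac_pair(0.8, seed=0)
        c = pac_comodulogram(slow, fast, FS, random_state=0)
        i, j = np.unravel_index(np.argmax(c.raw), c.raw.shape)
        assert (c.phase_freqs[i], c.amp_freqs[j]) == (3.0, 30.0)

    def test_preferred_phase_bin_recovered(self):
        phase0 = 1.2
        slow, fast = make_pac_pair(0.8, seed=1, phase0=phase0)
        c = pac_comodulogram(slow, fast, FS, random_state=0)
        i = int(np.flatnonzero(c.phase_freqs == 3.0)[0])
        j = int(np.flatnonzero(c.amp_freqs == 30.0)[0])
        best = int(np.argmax(c.profiles[i, j]))
        centers = -np.pi + (np.arange(c.n_phase_bins) + 0.5) * 2 * np.pi / c.n_phase_bins
        err = np.angle(np.exp(1j * (centers[best] - phase0)))
        assert abs(err) <= 2 * np.pi / c.n_phase_bins + 1e-9

    def test_strong_coupling_significant(self):
        slow, fast = make_pac_pair(0.8, seed=2)
        s = pac_summary(pac_comodulogram(slow, fast, FS, random_state=0))
        assert s.significant and s.z_mean > PAC_Z_CRITICAL

    def test_matrix_zscore_is_standardized(self):
        slow, fast = make_pac_pair(0.4, seed=3)
        c = pac_comodulogram(slow, fast, FS, random_state=0)
        assert c.z.mean() == pytest.approx(0.0, abs=1e-12)
        assert c.z.std() == pytest.approx(1.0, abs=1e-9)

    def test_threshold_is_strict(self):
        c = Comodulogram(
            phase_freqs=np.array([3.0]),
            amp_freqs=np.array([30.0]),
            raw=np.zeros((1, 1)),
            z=np.zeros((1, 1)),
            n_phase_bins=20,
            summary_z=PAC_Z_CRITICAL,
        )
        assert not pac_summary(c).significant

    def test_zero_coupling_not_significant(self):
        slow, fast = make_pac_pair(0.0, seed=4)
        s = pac_summary(pac_comodulogram(slow, fast, FS, random_state=0))
        # one null draw: overwhelmingly below threshold
        assert s.z_mean < PAC_Z_CRITICAL

    def test_insufficient_data_rejected(self):
        with pytest.raises(LengthError):
            pac_comodulogram(np.zeros(int(30 * FS)), np.zeros(int(30 * FS)), FS)
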