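# Methods

This note documents the models and estimators the package implements, the
parameter choices that matter, what the synthetic generator does and does
not emulate, and the numerical decisions made where the design was open.

## Signals and preprocessing

All narrowband filtering is a third-order Butterworth bandpass applied
forward–backward (`sosfiltfilt`, reflect padding of 3× the filter order).
Forward–backward application squares the magnitude response (effective
sixth-order attenuation) and cancels the phase response exactly; this is
the only construction in which a Butterworth filter is strictly
phase-preserving, which matters because every downstream coupling measure
(envelope correlation, PAC phase binning) assumes zero group delay.
Envelope and phase come from the Hilbert analytic signal; the first and
last 0.5 s of any envelope/phase series are treated as edge-contaminated
and excluded by consumers (`edge_slice`). Constant inputs have no defined
phase and are flagged with a warning rather than silently returning
garbage.

Wavelet denoising (used on the 1 s gPDC segments) follows the universal
soft-threshold recipe: Daubechies-4 decomposition to level
min(5, ⌊log₂ n⌋ − 2), noise scale σ̂ = MAD(finest details)/0.6745,
threshold σ̂·√(2 ln n), soft-thresholding of all detail levels. These are
the standard defaults of the classic wavelet-shrinkage literature and the
closest documented equivalent of common toolbox defaults.

Morlet time–frequency maps use a complex Morlet wavelet with a
constant-Q parameterization: at analysis frequency f the Gaussian
envelope has σ_t = cycles/(2πf), with cycles = 7 by default — enough
frequency resolution to separate RR from theta while keeping sub-second
time resolution.

## Spectra and band power

Welch PSD: Hamming tapers, non-overlapping windows of 2 s (0.5 Hz
resolution), one-sided per-Hz density, constant detrend. Non-overlapping
windows are deliberate (rather than the more common 50% overlap): with
minutes of stationary data the variance penalty is negligible and the
estimator is simpler to reason about. Band power is the trapezoidal
integral of the density over the half-open band [low, high); the bands are
RR 2–4, theta 4–12, beta 12–30 Hz. The estimator is Parseval-consistent:
a unit sine concentrates ≈ a²/2 in its band (within taper leakage, a few
percent).

The pre/post power modulation index (post − pre)/(post + pre) is bounded
in [−1, 1], antisymmetric under epoch swap, and undefined (a typed error)
when both epochs carry zero power.

## Amplitude correlation

Per 2 Hz band with lower edges 1, 3, …, 29 Hz (the last bin truncated to
29–30 Hz), both channels are bandpassed, Hilbert-enveloped, edge-cropped
and correlated (Pearson). Note the statistical resolution: a 2 Hz-wide
envelope decorrelates over ~0.5 s, so a 60 s recording gives only ~120
effective samples per bin and a null spread of |r| ≈ 0.1; interpretation
of single-recording values below that scale is noise.

## MVAR and gPDC

MVAR models are fitted by ordinary least squares on lagged-value design
matrices; the residual covariance uses the (n_obs − k·p) denominator.
Stability is assessed by the spectral radius of the companion matrix;
unstable fits are flagged, and the segment-averaging pipeline drops them
(erroring if more than half the segments fail). A sample-size guard
requires n ≥ 10·k·p.

gPDC is evaluated from the frequency response
Ā(f) = I − Σᵣ Aᵣ e^(−2πifr/fs): gPDC_{i←j}(f) = (|Āᵢⱼ|/σᵢ) /
√(Σₖ |Āₖⱼ|²/σₖ²). The column normalization Σᵢ gPDC² = 1 per source and
frequency is an algebraic identity and is enforced in tests at 1e-6; the
vectorized evaluation is checked against a scalar-loop reference at 1e-10.

The pipeline mirrors how such analyses are run on real recordings: one
LFP channel per area, cut into 1 s segments, each segment
wavelet-denoised and decimated to fs_model = 100 Hz (anti-aliased; the
analysis band ends at 30 Hz, and a low model rate keeps the coefficient
count small), then fitted and averaged over segments.

**Model order.** The order is fixed at p = 2 by default. With 1 s
segments at 100 Hz, the sample-size rule caps the usable order at 3, and
AIC on these data selects 3 — but null-coupling simulations (all directed
gains and PAC off) show that order-3 fits carry enough coefficient noise
to inflate spurious directed influence *out of* a strongly
autocorrelated narrowband source (mean forward/reverse asymmetry ≈ 0.05),
a known pathology of PDC-family estimators, while order-2 nulls are
symmetric (asymmetry ≈ 0.002) and order-2 fits still recover a true
OB→CA1 coupling decisively (0.51 vs 0.23 mean RR-band gPDC at gain 0.6).
AIC selection over the feasible range remains available
(`order="aic"`).

Averaged gPDC magnitudes from short segments have a positive noise floor
(≈ 0.2 here); only contrasts between directions or groups are meaningful,
not absolute values.

## Phase–amplitude coupling

Comodulograms cover slow phase frequencies 1–4 Hz (1 Hz steps, ±0.5 Hz
bands) × fast amplitude frequencies 12–50 Hz (2 Hz steps, ±5 Hz bands).
The amplitude bandwidth must admit the modulation sidebands (carrier ±
phase frequency, up to 4 Hz) — a narrower band would filter the
modulation away; ±5 Hz covers all slow frequencies analyzed. Phase and
envelope series are edge-cropped and subsampled to 50 Hz before binning
(envelopes of ±5 Hz bands fluctuate below 10 Hz, so 50 Hz loses nothing;
it makes the surrogate ensemble cheap). Coupling strength per cell is the
Tort modulation index: the KL divergence of the 20-bin phase-binned
mean-amplitude profile from uniform, normalized by log 20, in [0, 1].

Two z-scorings are provided. The default display matrix standardizes the
raw MI matrix across its entries (mean 0, SD 1), which shows *where*
coupling concentrates. The significance call, however, needs a null
reference: the summary statistic (mean raw MI over RR-phase rows 2–4 Hz ×
amplitude columns 13–50 Hz) is standardized against 200 circular
time-shifts of the amplitude envelopes (shift ≥ 1 s, phase series fixed),
which preserves each series' spectrum and marginal distribution while
destroying phase–amplitude alignment. Coupling is significant when this
surrogate-calibrated z strictly exceeds 1.96 (the two-sided standard
normal critical value at α = 0.05). The matrix z-score cannot serve here:
the summary subset is 57 of the 80 matrix cells, so its mean of
matrix-standardized values is pinned near zero by construction under null
and coupled data alike. Because the surrogate z is one-sided but
thresholded at the two-sided critical value, the null exceedance rate is
≈ 2.5–3.5% (measured 5/200 and 7/200 in two 200-run calibrations), i.e.
the test is slightly conservative at the conventional threshold.
A per-cell surrogate z matrix is available via `zscore="surrogate"`.

## Spike layer assignment

The mitral cell layer is localized by the RR polarity reversal: all OB
channels are RR-bandpassed and adjacent channels correlated; exactly one
anticorrelated pair marks the reversal, and the shallower member is
returned. Zero or multiple candidate pairs raise a detection error
carrying the correlation profile. Units within ±1 channel of the
reversal are MCL; units more than 3 channels deeper are GCL ("deeper"
reads toward the granule cell layer, consistent with a ventral-surface
probe insertion); the two channels between the rules stay unassigned by
design, so the rules can never overlap. Firing rate is spike count over
duration.

## Behavior

The arena is a 17.5 cm corridor: odor zones [0, 6.5) and [11, 17.5] cm,
neutral [6.5, 11). Zone membership uses the tracked nose x-coordinate;
frames below the tracking-likelihood threshold (default 0.9) are excluded
and counted, and zone times plus excluded time reconstruct the session
frame-exactly. The discrimination index is the difference-over-sum of
test- and control-zone dwell time (the only form that is signed, bounded
and consistent with the call-rate modulation index); it negates exactly
under side swap. The USV modulation index counts call onsets in
half-open disjoint windows.

## Synthetic generator

The generator produces what the pipeline consumes, with the statistical
features the analyses rely on, and logs every parameter:

- **OB probe (16 channels, 50 µm-type geometry).** A noise-driven
  narrowband oscillator at rr_freq (default 3 Hz, ±0.4 Hz band) is the
  respiration rhythm; its sign flips on channels deeper than mcl_index
  (default 8), giving the polarity reversal. Weaker theta (6–10 Hz) and
  beta (15–25 Hz) narrowband components and per-channel 1/f noise
  (exponent 1, SD noise_sd = 0.3) complete each channel. Default band
  power ratios RR:theta:beta = 1:0.3:0.1, matching the RR-dominated
  spectra of neonatal OB.
- **Coupling.** CA1 and PFC receive delayed, scaled copies of the OB
  oscillation (gains 0.6 / 0.4, delays 20 / 30 ms) plus CA1→PFC coupling
  (0.3, 10 ms) and independent 1/f noise; the coupled cores are
  multiplied by smoothed ON/OFF burst gates (exponential epochs, mean ON
  2.5 s, recurrence 0.2 Hz, ~50% duty) to emulate the discontinuous
  activity of immature cortex without modeling its biophysics.
- **PAC.** A 30 Hz component in CA1/PFC has envelope
  1 + depth·cos(φ_RR − φ₀) with depth 0.8 by default.
- **Spikes.** Inhomogeneous Poisson trains (thinning), rate modulated by
  the local RR phase (κ = 0.5); MCL units at 2 Hz on channels
  mcl ± 1, GCL at 1 Hz on channels > mcl + 3, CA1/PFC units at 1.5 Hz.
  The time-averaged rate equals the configured rate.
- **Behavior.** A reflected random walk (step SD 0.15 cm/frame at
  30 fps) with constant drift zone_bias (default 0.001 cm/frame) toward
  the test side; realized dwell times are logged with the same zone
  mapping the analysis uses, so occupancy recovery is frame-exact. Calls
  are piecewise-homogeneous Poisson (0.4 Hz) over the citral session
  template (90 s air / 60 s odor / 60 s air / 60 s break × 3 ascending
  concentrations) with suppression factor 0.25 during odor in the
  highest-concentration trial only.

Sampling rate is 1000 Hz: the analysis lives below 100 Hz, and
desk-scale simulation at acquisition-grade rates (tens of kHz) would buy
nothing. All randomness derives from the config seed; identical configs
are bit-identical.

**What the generator does not emulate** — and hence what passing recovery
tests do not show about real data: volume conduction and shared
references between probes, non-stationarity across a session (state
changes, electrode drift), odor-evoked transients, spike-sorting errors,
realistic LFP waveform shape (the rhythm is Gaussian narrowband noise,
not sharp-trough respiration coupling), tracking identity swaps, or call
segmentation errors. Recovery results certify the estimators and the
pipeline plumbing, not robustness to these real-world failure modes.

## Statistics

Two-group comparisons are gated by per-sample Shapiro–Wilk normality at
α = 0.05 (the conventional choice where the gate itself is unspecified):
both normal → t test (paired or unpaired), otherwise Wilcoxon signed-rank
(paired, zero-split handling of ties) or rank-sum. Two-factor designs
delegate to a type-II two-way ANOVA with interaction. Bonferroni
correction multiplies by the family size and caps at 1; the natural
family here is the three bands per measure per area pair. Constant
samples are routed to the rank branch (Shapiro is undefined on them), and
identical paired samples return p = 1.

## Pipeline and determinism

`run_pipeline` executes simulate → band power → amplitude correlation →
gPDC → PAC → spikes → behavior from a single YAML/JSON config and seed,
writing tidy CSVs (numbers printed at 6 significant digits), comodulogram
matrices, a summary JSON with the config hash, and a log. A stage failure
aborts with the stage name and marks outputs partial. Identical
(config, seed) reproduce every CSV byte-for-byte; this is asserted in the
test suite.

Default problem sizes in the test and reproduction studies (600 s × 20
seeds for direction recovery, 200 + 100 runs of 60 s for PAC calibration
and power, 20 + 20 reversal fixtures, n = 10⁵ for MVAR recovery) keep a
full run in the low minutes on one CPU while leaving the binomial and
estimator error bars well inside the asserted bounds.

## Known limitations

- gPDC values from 1 s segments carry a positive noise floor; use
  contrasts, not absolute magnitudes.
- The PAC significance call is conservative (~2.5–3.5% realized false
  positive rate at the 1.96 threshold; see above).
- Amplitude-correlation bins are statistically coarse below |r| ≈ 0.1 at
  60 s.
- The statistics module covers the two-group and two-factor designs used
  here, not general linear modeling.
- The container format is a deliberate minimal flat binary + JSON
  sidecar; vendor formats and standardized archives are out of scope.
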