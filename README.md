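# neocoupling

Analysis pipeline for multi-area extracellular recordings from neonatal
mice, built for the question of how spontaneous olfactory bulb (OB)
activity drives the developing hippocampal–prefrontal (CA1/PFC) network.
It is aimed at developmental-electrophysiology labs who record
simultaneously from OB, CA1 and PFC with linear silicon probes, track pup
behavior, and need the whole measurement chain — spectra, coupling
measures, spike layer assignment, behavior indices, group statistics — as
tested, scriptable code rather than ad hoc analysis scripts.

Because raw animal recordings are rarely shareable, the package ships a
synthetic data generator that emulates the statistical structure such
recordings have (a polarity-reversing 2–4 Hz respiration rhythm on the OB
probe, burst-gated CA1/PFC activity, directed inter-areal coupling,
phase–amplitude coupling of known depth, phase-locked Poisson spiking,
biased arena walks and Poisson call trains) and records every generating
parameter, so each analysis stage is verified end-to-end by parameter
recovery on known ground truth.

## What it computes

**Spectral.** Welch power spectral density (Hamming tapers,
non-overlapping 2 s windows) and band power in the respiration-rhythm
(RR, 2–4 Hz), theta (4–12 Hz) and beta (12–30 Hz) bands; Morlet
time–frequency maps; the pre/post power modulation index
MI = (post − pre)/(post + pre).

**Amplitude correlation.** Pearson correlation of Hilbert envelopes per
2 Hz band from 1–30 Hz between area pairs (non-directed coupling).

**Directed coupling (gPDC).** Generalized partial directed coherence from
multivariate autoregressive (MVAR) models. With
Ā(f) = I − Σᵣ Aᵣ e^(−2πifr/fs) and residual variances σₖ²,

    gPDC_{i←j}(f) = (|Āᵢⱼ(f)|/σᵢ) / sqrt(Σₖ |Āₖⱼ(f)|²/σₖ²)

so Σᵢ gPDC²_{i←j}(f) = 1 for every source j. The pipeline wavelet-denoises
1 s segments, decimates to 100 Hz, fits per-segment OLS MVAR models, drops
unstable fits and averages the gPDC magnitude.

**Phase–amplitude coupling (PAC).** Tort modulation-index comodulograms
between slow OB phase (1–4 Hz) and fast CA1/PFC amplitude (12–50 Hz),
z-scored, with a surrogate-calibrated summary of RR-phase → 13–50 Hz
coupling thresholded at z = 1.96.

**Spikes.** Mitral-cell-layer localization from the RR polarity reversal
on the OB probe (the unique anticorrelated adjacent channel pair), layer
assignment of sorted units (MCL = reversal ± 1 channel, GCL = deeper than
reversal + 3), and firing rates.

**Behavior.** Odor–place preference in a 17.5 cm two-odor-zone arena
(discrimination index DI = (t_test − t_control)/(t_test + t_control) from
nose tracking) and ultrasonic-vocalization suppression
(MI = (rate_during − rate_before)/(rate_during + rate_before)).

**Statistics.** Normality-gated two-group tests (Shapiro–Wilk gate;
t tests or Wilcoxon rank tests), two-way ANOVA, Bonferroni correction.

## Worked example

Run the full pipeline on a synthetic 60 s triple-area session:

```bash
neocoupling analyze --seed 7 --out results/demo
```

or equivalently, from Python:

```python
from neocoupling import run_pipeline
run_pipeline({"synthetic": {"duration_s": 60.0}}, "results/demo", seed=7)
```

This writes six result CSVs plus two comodulogram matrices, a
`summary.json` and a log. Selected output for seed 7:

`band_power.csv` — OB power is RR-dominated, as in real neonatal OB:

```
recording_id,area,band,power
synthetic,OB,RR,0.779403
synthetic,OB,theta,0.325642
synthetic,OB,beta,0.121759
```

`gpdc.csv` — the directed OB→CA1 influence exceeds the reverse direction
in the RR band (the generator couples OB→CA1 with gain 0.6):

```
OB->CA1,RR,0.429438
CA1->OB,RR,0.263861
```

`pac.csv` — the injected phase–amplitude coupling (depth 0.8 at 30 Hz) is
detected far above the z = 1.96 significance level:

```
pair,z_mean,significant
OB-CA1,23.3513,1
OB-PFC,24.2035,1
```

`firing_rates.csv` — MCL units configured at 2 Hz are estimated near 2 Hz
(`0,MCL,2.16667`), and `summary.json` reports the detected reversal
channel (`"mcl_channel": 8`, the generator's ground truth).

`behavior.csv` — the biased walk yields a positive discrimination index
(0.683884) and calls are suppressed only in the highest-concentration
odor trial (`usv_mi_trial2,-0.733333`, against an expected −0.6 for the
configured 4-fold suppression).

`neocoupling simulate --seed 3 --out fixtures/` writes the raw fixture
set instead (binary recording + JSON sidecar, spike/track/call/event
CSVs, ground-truth JSON) for use with the library functions directly.

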