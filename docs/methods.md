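# Methods

This note documents the models, parameter choices and numerical decisions
behind `fnirsdep`, and what the synthetic-cohort tests do and do not
establish about real recordings.

## Synthetic cohort model

Each subject's clean ΔHbO trace per channel is `a_c · r(t)`, where `r(t)`
is the task boxcar (samples 300–900 of a 1200-sample, 10 Hz recording)
convolved with a canonical double-gamma HRF (positive gamma peaking
~5–6 s, undershoot gamma at ~15 s scaled by 1/6; unit peak).  ΔHbR is
−1/3 of ΔHbO lagged by 1 s — a typical empirical amplitude ratio and lag.

The per-channel amplitude is
`a_c = μ(group) + b + w_c`, with subject latent `b ~ N(0, σ/√2)` and
independent channel deviations `w_c ~ N(0, σ/√2)`, σ = 0.3, clipped below
at 0.05 (amplitudes are physical).  Group means are μ(severe) = 1.0 and
μ(mild) = 1.0 + effect_size·σ, so `effect_size` is the standardized
per-channel group difference.  Splitting the amplitude variance between a
subject latent and channel-level deviations matters: with a single
subject latent, the best achievable accuracy at effect 2.0 would be
Φ(1) ≈ 0.84 regardless of channel count, whereas a spatially distributed
effect — the physiologically realistic case — lets multichannel
classifiers aggregate evidence.

Nuisance components per channel and species: a cardiac sinusoid
(subject frequency ~N(1.1, 0.15) Hz clipped to 0.55–1.95 Hz, amplitude
0.25), a respiratory sinusoid (~N(0.30, 0.03) Hz clipped to 0.21–0.39 Hz,
amplitude 0.3), a linear drift (slope uniform within ±0.4 over the
recording), white noise (σ = 0.15), and Poisson-placed motion artifacts
(rate 2 per recording; spikes are Gaussian bumps of 0.5 s width, shifts
are step offsets, amplitudes 2–5 × a 0.5 base scale).  HbR noise scales
by 1/3 with the signal.  All amplitudes are in the same arbitrary
concentration unit as the evoked response; every feature downstream is
either scale-covariant or scale-invariant, so the unit convention does
not affect selection or classification.

What the generator does **not** emulate: spatially correlated
physiological noise across channels (each channel's nuisance draws are
independent except for shared subject frequencies), superficial-layer
contamination, heteroscedastic optode coupling, serial correlation beyond
the modelled sinusoids, and any nonlinear coupling between depression
severity and noise structure.  Passing tests therefore demonstrate that
the pipeline recovers a planted amplitude effect under realistic noise
magnitudes — not that real mild/severe cohorts are separable at any
particular accuracy.

All randomness flows from one integer seed through
`numpy.random.SeedSequence` spawning; identical seeds give bit-identical
cohorts.

## Preprocessing

* **Beer–Lambert conversion**: per channel and sample the 2×2 system
  ΔOD_λ = ε_λ,X · d · DPF_λ · ΔX is solved with d = 3.0 cm,
  DPF = (6.0, 5.0) and extinction coefficients (660 nm: 320 / 3227,
  830 nm: 974 / 693, in 1/(cm·M)) from the standard compiled tables;
  outputs in µM.
* **Detrending**: least-squares polynomial (default order 3) on a
  [−1, 1]-scaled abscissa for conditioning.
* **TDDR**: the published robust reweighting on the temporal derivative
  (Tukey biweight, tuning constant 4.685, σ = 1.4826·MAD, iterated to
  μ-convergence 1e-9 or 50 iterations), applied to the sub-0.5 Hz part
  and reintegrated, with the high-frequency part added back unchanged.
  One deliberate deviation from the reference realization: the 0.5 Hz
  split uses a 21-tap linear-phase FIR instead of a Butterworth IIR.  The
  IIR's long impulse-response tails smear a step artifact's derivative
  below the robust threshold (only ~87% of a step removed); the compact
  FIR keeps artifact derivatives outlying (~94% removed) without
  affecting smooth content.
* **Band filter**: two third-order Chebyshev-II sections, 30 dB stopband
  attenuation — low-pass with stopband edge 0.2 Hz, then high-pass with
  critical frequency 0.01 Hz — each applied forward-backward with
  constant-extension padding.  Low-pass-first ordering and constant
  padding are load-bearing: the 0.01 Hz high-pass has an impulse response
  comparable to the recording length, and other orderings leak its edge
  transients broadband (a 1 Hz tone is then suppressed to only ~11% RMS
  instead of <1%).  The 0.01/0.2 Hz reading ("cutoff"/"stopband") is one
  of two defensible interpretations of the filter description; a pure
  low-pass with detrending handling the drift side would also be
  coherent, and the high-pass section can be disabled.
* The pipeline (detrend → TDDR → filter) is *not* idempotent: the
  passband of this filter specification is narrow and non-flat (measured
  forward-backward gain 0.98 at 0.05 Hz, 0.75 at 0.08 Hz), and TDDR's
  Tukey weights shrink inlier derivatives on every pass.  The test suite
  asserts bounded stability (a second pass changes the result by <10% of
  what the first pass changed) rather than idempotence.

## CEEMDAN-WPT

EMD uses cubic-spline envelopes through strict local extrema with two
extrema mirrored about each signal edge; sifting stops at a
standard-deviation criterion < 0.2 or 10 iterations; decomposition stops
when the residual has fewer than two interior extrema (at most 12 modes).

CEEMDAN defaults: ensemble I = 100 (tests and the acceptance script use
I = 30 — reconstruction exactness is independent of I and the benchmark
orderings are stable there, so the smaller ensemble is used for the
routinely-run problem sizes), noise scale ε = 0.2·std(x), one seeded
generator for all noise realizations.  Each realization is pre-decomposed
once and its k'th mode injected at stage k (the realization itself at
stage 0).  Because every stage subtracts its ensemble-averaged mode from
the running residual, Σ modes + residual telescopes to the input exactly
(float round-off only); the test suite asserts ≤ 1e-8 × RMS pointwise.

Wavelet-packet thresholding: db4, level 3, soft universal threshold
λ = σ̂·√(2 ln n).  Two σ̂ conventions are provided.  For noise-dominated
IMFs (the CEEMDAN-WPT path) σ̂ is estimated per packet node — this is
what removes in-band cardiac energy concentrated in one node.  For
whole-signal wavelet filtering (the comparison baseline) σ̂ comes from
the highest-frequency packet only, the standard practice; per-node
thresholds applied to a whole signal would annihilate signal-dominated
packets.  The lowest-frequency (approximation) band is never thresholded.

IMFs are split at a mean zero-crossing rate of 0.4 Hz (twice the filter's
low-pass stopband edge).  The thresholding path falls back to "first
⌈K/2⌉ modes are high" when the rule selects none (harmless: thresholding
clean modes preserves them); the plain-EMD baseline, which discards its
high modes outright, uses no fallback, since discarding modes that are
not noise would destroy signal.

The denoising benchmark battery consists of 20 simulated subjects whose
noise is restricted to the residual in-band profile (cardiac + white,
no drift/respiration/artifacts): decomposition denoising in this pipeline
runs after detrending and band filtering, so drift and respiration are
already gone, and both fall below the 0.4 Hz split where no decomposition
method would act on them.  SNR is reported both against the clean
reference and against the noisy input, since published benchmarks often
leave the convention unstated.

## Features

All features are computed on the 60-s task window (samples [300, 900)).
The periodogram is the plain unwindowed one-sided FFT periodogram;
entropies use natural log (any base is a monotone rescaling).  Mean
squared frequency is Σ f² P(f) / Σ P(f).  Singular spectral entropy
embeds the signal in a Hankel matrix of window 50 samples (5 s).
Constant signals receive defined sentinels (skewness 0, peak factor 1)
and log a warning; zero-variance channels yield Pearson r = 0 for their
pairs.  Column order is deterministic: TF by (kind, channel, species),
then CF by (species, pair).

A subtlety the tests encode: white-noise periodogram entropy does not
approach ln(bins) — periodogram ordinates are exponentially distributed,
giving E[H_f] = ln N − (1 − γ) with γ Euler's constant.

## Selection and classification

RFECV uses a linear SVM (C = 1) with coefficient magnitudes as
importances, elimination step 1, stratified 5-fold CV, accuracy scoring;
ties in the CV curve resolve to the smaller subset.  Features are
z-scored over the table being selected on, which per the leakage contract
holds training subjects only; a sentinel test plants a feature that is
class-aligned only on held-out subjects and asserts it is not selected.

The 60/40 split rounds half-up per class (82/58 → 49/35 train,
33/23 test).  Grid search is exhaustive over: SVM {C ∈ 10^(−2..2),
linear or RBF with γ ∈ {scale, 10^(−3..0)}}, LR {C ∈ 10^(−2..2)},
RF {100/300 trees × depth 3/5/∞}, MLP {16 or 64 hidden units ×
L2 ∈ {1e-4, 1e-2}}; ties take the first lattice entry, and rows are
canonicalized by subject id so results do not depend on input order.
Nested CV is 5 × 5 stratified; scaling lives inside the fold pipeline.
The positive class for sensitivity/AUC is "severe".  The calibration
tests (and the acceptance script) use the linear-kernel SVM grid: the
margin classifier is the family the fusion comparison is defined over,
and the reduced lattice keeps the routine runtime small.

Group comparison of GLM betas uses a two-sample Welch t-test with sign
convention mild − severe.  (A paired test is impossible for independent
groups of 82 and 58.)  Significance is raw p < 0.05 per channel by
default, matching the per-channel activation-map convention; Bonferroni
correction is available but off by default.

## Known limitations

* EMD envelope end-conditions use two-point mirroring; other boundary
  rules change mode shapes near the edges.
* The CEEMDAN ensemble average is O(I · K) first-mode extractions per
  signal; full-cohort denoising is therefore offered per recording in the
  CLI but not forced into the feature pipeline.
* The classification accuracies reported by the acceptance script are
  properties of the synthetic generator at the stated effect size, not
  estimates of clinical performance.
* SNIRF support is read-only and limited to processed HbO/HbR blocks.
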