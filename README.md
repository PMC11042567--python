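# fnirsdep

Decision support for grading depression severity (mild vs. severe) from
prefrontal functional near-infrared spectroscopy (fNIRS) recordings taken
during a verbal fluency task (VFT).

fNIRS measures task-evoked changes in oxygenated (ΔHbO) and deoxygenated
(ΔHbR) hemoglobin through scalp-mounted optode pairs.  Prefrontal
activation amplitude during cognitive load differs systematically between
mild and severe depression (mild > severe), which makes the hemodynamic
response a candidate objective marker where diagnosis otherwise rests on
clinical interview.  This package implements the full analysis chain a
clinical research group would run on such data, and — because clinical
recordings of this kind cannot be shared — ships a statistically matched
synthetic cohort generator so every stage is testable end to end.

## Pipeline

1. **Simulation** (`fnirsdep.simulate`): block paradigm (30 s rest / 60 s
   task / 30 s rest at 10 Hz, 18 prefrontal channels), boxcar ⊗
   double-gamma HRF responses, cardiac (0.5–2.0 Hz) and respiratory
   (0.2–0.4 Hz) oscillations, drift, broadband noise, spike/shift motion
   artifacts, and a configurable standardized group difference in evoked
   amplitude.  Clean ground-truth traces are retained for true-SNR
   validation.
2. **Preprocessing** (`fnirsdep.preprocess`): modified Beer–Lambert
   conversion of optical densities, polynomial detrending, temporal
   derivative distribution repair (TDDR) motion correction, and a
   zero-phase third-order Chebyshev-II band filter (0.01 Hz high-pass
   edge, 0.2 Hz low-pass stopband).
3. **CEEMDAN-WPT denoising** (`fnirsdep.denoise`): complete ensemble
   empirical mode decomposition with adaptive noise.  Stage k adds
   ε·E_k(ω_i) — the k'th EMD mode of white noise ω_i — to the running
   residual, extracts the first EMD mode of each of the I perturbed
   copies, and averages; the input is recovered exactly as Σ modes +
   residual.  High-frequency modes (zero-crossing rate > 0.4 Hz) are
   wavelet-packet soft-thresholded (db4, level 3, universal threshold)
   and the signal reassembled.  Quality is scored by
   SNR = 10·log₁₀(Σx²/Σ(x−y)²) and RMSE = √(Σ(x−y)²/N).
4. **Features** (`fnirsdep.features`): per channel and species on the
   60-s task window — maximum, minimum, mean, rectified mean, skewness,
   peak (crest) factor, mean squared frequency, power spectral entropy
   H_f = −Σ p_k ln p_k over the normalized periodogram, and singular
   spectral entropy H_t over normalized Hankel-matrix singular values:
   18×2×9 = 324 temporal features (TF).  Pearson correlations of every
   channel pair per species: C(18,2)×2 = 306 correlation features (CF).
5. **Selection** (`fnirsdep.select`): two-pass recursive feature
   elimination with cross-validation (RFECV, linear SVM importances) —
   TF and CF screened separately, survivors fused, final subset
   re-selected.  Selection only ever sees training subjects.
6. **Classification** (`fnirsdep.classify`): stratified 60/40 split,
   grid-searched RF / LR / MLP / SVM, nested cross-validation (inner loop
   tunes, outer loop scores), metrics: AUC, accuracy, sensitivity,
   specificity, F1.
7. **Group statistics** (`fnirsdep.groupstats`): per-subject GLM betas
   against the HRF regressor, one-sample channel activation t-tests, and
   a Welch t contrast of activation between groups (mild − severe).

## Worked example

Benchmark the denoising methods on ten synthetic subjects whose recordings
carry the task response plus residual in-band noise (cardiac + broadband),
scoring each method against the known clean traces:

```python
from fnirsdep.simulate import CohortSpec, NoiseProfile, simulate_cohort
from fnirsdep.denoise import CeemdanConfig, benchmark_denoisers

profile = NoiseProfile(cardiac_amp=0.25, resp_amp=0.0, drift_amp=0.0,
                       white_sigma=0.15, artifact_rate=0.0)
cohort = simulate_cohort(CohortSpec(n_severe=5, n_mild=5, n_channels=2,
                                    seed=7, noise_profile=profile))
for rep in benchmark_denoisers(cohort,
                               ceemdan=CeemdanConfig(ensemble_size=30, seed=0)):
    print(f"{rep.method:12s} SNR={rep.snr_vs_clean_db:6.2f} dB  RMSE={rep.rmse:.4f}")
```

```
raw          SNR= 10.21 dB  RMSE=0.2328
emd          SNR= 23.71 dB  RMSE=0.0492
wavelet      SNR= 21.79 dB  RMSE=0.0598
ceemdan-wpt  SNR= 22.42 dB  RMSE=0.0557
```

`raw` is the untouched noisy signal (10.2 dB against the clean
reference).  All decomposition-based methods roughly double the SNR;
CEEMDAN-WPT beats whole-signal wavelet thresholding because only the
noise-dominated high-frequency modes are thresholded while the task-band
content passes through untouched.

The same pipeline is available from the shell:

```bash
fnirsdep run-all --out-dir runs/demo --effect-size 2.0 --seed 3
```

which writes the cohort, feature tables, selection report, evaluation
report and activation statistics into a self-describing run directory.

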