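# eegbeta

Relative EEG beta-band power as a sex biomarker: an end-to-end, testable
re-implementation of the analysis pipeline — synthetic cohort generation,
artifact cleaning, spectral features, and logistic classifier evaluation.

Because the underlying clinical EEG data are not publicly deposited, the
package ships a first-class synthetic-data module that generates seeded
19-channel (10–20 montage) resting-state cohorts with a controllable sex
effect on beta amplitude, paired pre/post sessions with a configurable
cross-session correlation, and injectable artifacts (flat channels,
decorrelated channels, high-amplitude bursts) with machine-readable ground
truth. Every downstream stage is validated against that ground truth.

## Components

- `eegbeta.simulate` — seeded synthetic cohorts: 1/f background plus
  band-limited alpha (8–12 Hz) and beta (12–25 Hz) oscillations, spatially
  mixed through montage geometry; log-normal subject beta factors with a
  sex effect expressed as a log-scale Cohen's d (`effect_size_for_auc(0.75)`
  gives the default recovery scenario); artifact injection with logs.
- `eegbeta.preprocessing` — the cleaning chain as individually testable
  operators, applied in fixed order: resample (250 Hz) → trim 30 s edges →
  flat-channel detection (>5 s) → zero-phase high-pass (0.25/0.75 Hz
  transition) → correlation-based channel rejection (spherical-spline
  prediction score, threshold 0.75) → artifact subspace reconstruction
  (sliding-window PCA, std threshold 5) → bad-window rejection (1 s windows,
  66% overlap, >4 bad channels) → spherical-spline interpolation of removed
  channels → average reference → zero-phase 40 Hz FIR low-pass. A
  `CleaningReport` records everything that was removed or reconstructed.
- `eegbeta.spectral` — Welch PSD (2 s Hann segments, 50% overlap) that
  never bridges rejected windows; band powers on half-open bands
  δ[0.5–4) θ[4–8) α[8–12) β[12–25); relative beta = β / (δ+θ+α+β);
  per-subject feature tables (19 channels + channel mean, optional
  absolute-beta variant).
- `eegbeta.classify` — unpenalized logistic regression (IRLS, tiny-ridge
  fallback on separation), ROC/AUC with tie handling, constrained maximum
  accuracy (best pooled accuracy with TPR > 50% and FPR < 50%, positive
  class = males, the minority), balanced-subsample mean ROC (40+40 × 100,
  vertical averaging), leave-one-out validation, rank-sum channel selection
  inside cross-validation, and the six-model × two-session evaluation grid.
- `eegbeta.stats` — rank-sum test (exact for combined n ≤ 20, tie- and
  continuity-corrected normal approximation otherwise), Bonferroni
  correction, per-electrode sex tests, paired t-test, pre/post session
  correlations, misclassification overlap.
- `eegbeta.edf` — minimal 16-bit EDF reader/writer (no external EEG I/O
  dependency).

## CLI

```sh
eegbeta simulate --config cfg.yaml --out raw/ --seed 1
eegbeta clean --in raw/S0000_pre.edf --out clean/S0000_pre.edf --report rep.json
eegbeta features --in clean/ --meta raw/metadata.csv --out features.csv
eegbeta evaluate --features features.csv --session both --seed 1 --out eval/
eegbeta stats --features features.csv --out stats.csv
```

`simulate` writes EDF recordings, a metadata CSV and a JSON artifact
ground-truth log; `evaluate` emits the evaluation grid as CSV/JSON plus
per-model ROC point sets.

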