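# sonoforce

Ground-reaction-force prediction from M-mode muscle ultrasound, built as a
fully synthetic, tested pipeline. The package simulates contracting-thigh
imaging two ways — a clinical-style B-mode scanline and a wearable
frequency-sweep (FMCW) device whose depth is encoded as beat frequency and
recovered by FFT — extracts intensity-weighted mean-depth features from
moving depth windows, and predicts force with closed-form ridge regression
under a 5-fold cross-validation / held-out-trial protocol comparing six
model-input categories.

## Modules

| module | what it does |
|---|---|
| `sonoforce.phantom` | synthetic force profiles, tissue-interface kinematics, speckled M-mode rendering, multi-trial datasets (trials 1–2 train, trial 3 test) |
| `sonoforce.chirp` | frequency-sweep acquisition: beat-frequency depth encoding, baseband simulation, Hann-windowed FFT demodulation, M-mode stacking |
| `sonoforce.mmode` | M-mode/B-mode containers, scanline extraction, 16-bit PNG + JSON-sidecar image I/O, force CSV, YAML manifests |
| `sonoforce.features` | windowed mean depth (25 px windows, 50% overlap), z-scoring, PCA truncated at 99% explained variance |
| `sonoforce.ridge` | closed-form ridge fit (k = 5 default), prediction, 25-sample moving-average smoothing, R² |
| `sonoforce.evaluate` | six-model registry (clinical, distributed 4-site, each single site), 5-fold CV, held-out-trial testing, JSON/CSV reports |
| `sonoforce.cli` | `sonoforce simulate | features | fit | evaluate | report` |

## CLI quick start

```sh
sonoforce simulate --out data/ds --seed 1          # writes images + manifest
sonoforce evaluate data/ds/manifest.yaml --out results/eval --seed 1
sonoforce report results/eval/report.json          # per-model R² table
```

Every command writes its resolved configuration and seed next to its
outputs; reruns with the same seed are bit-identical.

## Conventions

- Depth axes use pixel centers: pixel *j* of *n* spans a window of depth
  *d* at (*j* + 0.5) · *d* / *n*; rows are depth (shallow first), columns
  are time.
- 1600 Hz force is aligned to the 50 Hz frame rate by block-mean
  decimation (factor 32).
- Feature windows stride by round(25 · 0.5) = 12 px; only full windows
  are kept (20 windows at 256 px depth, 9 at 128 px).
- The z-score/PCA transform is refit inside each CV fold by default
  (leakage-safe); a fit-once-globally mode is available.
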