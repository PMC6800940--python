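# pvcforest

Detection of premature ventricular contractions (PVCs) in single-lead ECG.
A PVC is an ectopic beat fired from the ventricles: on the ECG it shows a
wide, often taller (or inverted) QRS complex without a preceding P wave,
arrives early (short preceding RR interval) and is followed by a
compensatory pause. `pvcforest` implements the complete classical pipeline
that turns a raw 360 Hz recording into a per-beat PVC / non-PVC decision,
with every algorithmic component written from scratch and testable offline:

1. **WFDB I/O** — MIT-BIH-layout records: ASCII `.hea` headers, format-212
   `.dat` signals (two 12-bit two's-complement samples per 3 bytes), binary
   or text beat annotations; AAMI EC57 symbol grouping
   (N = {N,L,R,e,j}, S = {A,a,J,S}, V = {V,E}, F = {F}, Q = {/,f,Q}) and the
   standard DS1/DS2 22+22-record train/test split with paced records
   102/104/107/217 excluded.
2. **Wavelet denoising** — Daubechies-8, 5 levels, universal threshold
   σ√(2 ln n) with soft thresholding of detail coefficients
   (σ = median|d₁|/0.6745).
3. **Pan–Tompkins R-peak detection** — band-pass (5–15 Hz), derivative,
   squaring, 150 ms moving-window integration, adaptive dual thresholds with
   search-back, 200 ms refractory period and T-wave rejection; detections
   scored against references with the 150 ms one-to-one matching rule.
4. **Beat segmentation** — the inclusive window [R−100, R+150] (251 samples);
   QRS onset/offset by a sliding-window variance search: a 10-sample window
   split into 5-sample halves with variances S₁, S₂; a boundary is the point
   where a stationary baseline (S₁ ≤ τ, S₁ < S₂) meets five strictly
   monotone samples entering (or leaving) the complex.
5. **Features** — R_amp, PR, QRS, QT, QRS_area = QRS·R_amp, pre_RR, post_RR;
   classification uses the subset (pre_RR, post_RR, QRS_area, R_amp).
   Nothing is normalized.
6. **SMOTE** — minority oversampling by interpolation toward k = 5 nearest
   minority neighbours, x_new = x + r·(x′ − x), balanced to an exact target
   ratio (13:1 → 8:1 / 4:1 / 1:1).
7. **Random forest** — from-scratch CART trees (Gini impurity
   1 − Σp_k², splits minimize the size-weighted child impurity over all
   midpoint thresholds), bagging with recorded in-bag multisets,
   out-of-bag error estimation, majority-vote prediction.
   Defaults: 120 trees, min_samples_split = 100, min_samples_leaf = 30.
8. **Evaluation** — Acc, PPV, Se, Sp and Youden's index γ = Se + Sp − 1.

A synthetic generator (`pvcforest.synth`) produces labeled 360 Hz records
(Gaussian-bump beats with PVC morphology, noise, ground-truth R locations)
and labeled feature tables, so the full pipeline is verifiable without any
database download.

## Worked example

End-to-end synthetic experiment — generate a 13:1 imbalanced training table
(7000 beats), SMOTE-balance it to 1:1, train the forest, and test on an
independent 13:1 stream:

```
$ pvc pipeline --outdir demo --seed 1
   Acc: 0.9847
   PPV: 0.8370
    Se: 0.9760
    Sp: 0.9854
 gamma: 0.9614
```

97.6% of PVC beats are caught (Se) while 98.5% of normal beats pass
untouched (Sp), i.e. γ = 0.961; PPV is lower because the test stream is
heavily imbalanced (500 PVCs among 7000 beats). `demo/` now holds
`features.csv`, `balanced.csv`, `model.json` and `report.json`.

Signal-level stages work the same way from the shell:

```
$ pvc simulate --n-beats 220 --pvc-fraction 0.15 --seed 3 --out rec
wrote 220 beats (25 PVC) to rec
$ pvc detect --record rec/synth
220 R peaks detected
all=220 correct=220 wrong=0 missed=0 Se=1.0000 PPV=1.0000
```

`pvc features`, `pvc balance`, `pvc train` and `pvc evaluate` chain the
remaining stages over plain CSV/JSON files. Users with a local copy of the
MIT-BIH arrhythmia database can re-run the full study with
`pvc reproduce-mitbih --data-dir <dir>`; nothing is ever downloaded.

## Layout

```
src/pvcforest/     wfdb_io, denoise, qrs, beats, features, smote,
                   forest, evaluation, synth, pipeline, cli
tests/             unit + property tests and the system-level suite
scripts/           acceptance.py
docs/methods.md    models, parameters, numerical choices, limitations
```
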