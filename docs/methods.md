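# Methods

This note documents the models behind each pipeline stage, the parameters
that matter, what the synthetic generator does and does not emulate, and the
numerical choices made where the design was genuinely open.

## Signal model and denoising

The input is a single ECG lead (canonically MLII) sampled at `fs` = 360 Hz,
in millivolts. Denoising operates in the wavelet domain: `db8`
decomposition to 5 levels with periodization boundary handling, so the
transform is orthogonal (coefficient energy equals sample energy, verified
to 1e−6 relative in the tests). Detail coefficients are soft-thresholded
with the universal threshold t = σ√(2 ln n), σ estimated robustly from the
finest detail level as median|d₁|/0.6745 — the QRS complexes are sparse
there, so the median sees mostly noise. Soft thresholding guarantees the
output energy never exceeds the input energy. Both the rule (`universal` /
`fixed`) and the mode (`soft`/`hard`) are configurable; the level count must
satisfy 2^levels ≤ n.

Wavelet selection (`select_wavelet`) scores each candidate basis by the
peak absolute normalized cross-correlation between the signal and the
candidate's scaling (low-pass) filter, ties breaking toward the earlier
candidate. One caveat is worth recording: short filters correlate close to
1 with *any* smooth window, so this statistic discriminates only when the
signal actually contains filter-shaped transients; on very smooth signals
the shortest candidate tends to win regardless. The db8 default is
therefore the fixed pipeline choice, and selection is offered as a
diagnostic, not wired into `denoise`.

## R-peak detection

The detector follows the Pan–Tompkins architecture. Because the classic
integer-coefficient filters assume 200 Hz, the band-pass here is a 3rd-order
5–15 Hz Butterworth designed at run time for the actual `fs` and applied
forward-backward (zero phase), which keeps all stages aligned with the
input; the derivative is the standard five-point kernel, applied centered.
Squaring and a round(0.150·fs)-sample centered moving average complete the
stages.

Peak picking keeps running signal/noise peak estimates
(SPKI ← 0.125·peak + 0.875·SPKI on acceptance, NPKI likewise for rejected
candidates) with threshold NPKI + 0.25·(SPKI − NPKI), initialized from the
first two seconds. If the gap since the last beat exceeds 1.66× the mean of
the last eight RR intervals, a search-back re-examines skipped candidates at
half threshold (SPKI update 0.25/0.75). A candidate within 360 ms of the
previous beat whose maximal absolute derivative is less than half the
previous beat's is rejected as a T wave (configurable). Accepted decisions
are refined to the largest-magnitude band-passed sample within ±75 ms —
magnitude, not value, so negative-going PVC complexes refine correctly —
and a 200 ms refractory period is enforced on the final indices.

Detector scoring matches detections to reference beats one-to-one within
150 ms by a left-to-right two-pointer walk; on interval graphs over a line
this greedy matching is maximum-cardinality, which the tests confirm against
an exhaustive bipartite-matching oracle.

## Beat segmentation and QRS boundaries

A beat is the inclusive window [R−100, R+150]: 251 samples with R at local
index 100; local index 0 is treated as the P-wave start and 250 as the
T-wave end. Beats whose window leaves the record are dropped.

The boundary search slides a 10-sample window split into 5-sample halves.
For the onset, scanning i from the 4th point after the window start up to
R−8: S₁ = Var[Xᵢ₋₄..Xᵢ], S₂ = Var[Xᵢ₊₁..Xᵢ₊₅] (population variance,
divide by n); Xᵢ is accepted when S₁ < S₂, S₁ ≤ τ (stationary baseline) and
the five samples after Xᵢ are strictly monotone (all rising or all
falling — ties fail). The offset search mirrors this forward from R: five
strictly monotone samples leaving the complex followed by a stationary
window [Xⱼ..Xⱼ₊₄] with variance ≤ τ and below that of [Xⱼ₋₅..Xⱼ₋₁]. The
scan direction (outward from R on both sides) is our reading of an
operation whose offset-side ordering is ambiguous; the mirrored predicate
keeps the two searches exactly symmetric, which the tests exploit.

"Fluctuates around zero" needs a number: τ defaults to 2% of the largest
5-sample window variance anywhere in the beat, floored at 1e−6 mV². The
relative form makes the flatness test amplitude-scale-free, and the floor
keeps exactly flat baselines classifiable; both knobs are exposed. When no
index qualifies (flat beats, pathological morphology) the fallback sets
QRS_start = R−40 and QRS_end = R+40 (≈111 ms half-widths at 360 Hz), flagged
and logged, so every beat still yields a feature vector. On piecewise-linear
beats with known boundaries the localizer is exact (median error 0, bound
≤ 3 samples asserted); boundary search is invariant under constant amplitude
shifts because variance is.

## Features

Seven per-beat features (R_amp, PR, QRS, QT, QRS_area = QRS·R_amp, pre_RR,
post_RR), all in physical units (mV, s), none normalized — the forest does
not need standardized inputs, and leaving them raw keeps them clinically
interpretable. R_amp is read off the *denoised* beat with its sign
preserved (MLII PVCs can be negative-going). The first and last beats of a
record are excluded (no preceding/following RR interval). When training
labels come from annotations, detector false positives are removed *before*
RR computation, so RR features are computed on the cleaned beat sequence.
The classification subset (pre_RR, post_RR, QRS_area, R_amp) reflects the
single-feature importance ranking that `single_feature_importance`
recomputes: each feature alone trains a forest and is scored by correctly
identified PVC beats on an evaluation set.

## SMOTE

Balancing to a majority:minority target ratio: target minority count
= round(majority/ratio); N = ⌊majority/(minority·ratio)⌋ − 1 full
interpolation passes over the minority set, then a residual of randomly
chosen minority points closes the exact count (needed because 8:1 and 4:1
are not integer multiples of 13:1). k = 5 neighbours by Euclidean distance
(self excluded, ties by index); each synthetic point is
x + r·(x′ − x), r ~ U(0,1), hence componentwise between its parents. One
seeded generator drives everything in a documented order (per sample:
neighbour index, then r), so balancing is byte-reproducible. The majority
multiset is never modified.

## Forest

CART trees on continuous features: binary splits at midpoints of
consecutive distinct sorted values, chosen to minimize the size-weighted
child Gini impurity (the discrete-attribute form of the impurity index
generalizes to thresholds this way). Ties break toward the lowest feature
index, then the lowest threshold; a pure node is never split. Growth stops
at purity, below min_samples_split = 100, or when no split leaves both
children ≥ min_samples_leaf = 30; there is no pruning — the size controls
are the regularizer. Leaves predict their majority class; both leaf ties
and ensemble vote ties resolve to non-PVC, a documented (and debatable)
safe-side choice, configurable at the data level by thresholding
`predict_proba` instead. Feature subsampling per split defaults to ⌈√d⌉
(`"all"` recovers pure bagging). With T = 120 bootstrap trees and recorded
in-bag multisets, the out-of-bag estimate votes each training row only
through trees that never drew it; rows drawn by every tree are excluded and
counted. On a 4000-row synthetic task with 200 trees the OOB error sits
within 0.03 of an independent hold-out error (asserted), and the mean
unique in-bag fraction matches the bootstrap limit 1 − 1/e ± 0.02.

Models serialize to JSON (params, in-bag draws, nested nodes), so a saved
forest reproduces its predictions and OOB analysis exactly.

## Metrics

Acc = (TP+TN)/total, PPV = TP/(TP+FP), Se = TP/(TP+FN), Sp = TN/(TN+FP),
γ = Se + Sp − 1 (Youden's index), with PVC as the positive class. γ is
invariant under class-prevalence rescaling; Acc is not — which is why γ is
the headline number on imbalanced streams. Zero-denominator metrics are
reported as NaN with a warning, never as 0.

## Synthetic data: what it emulates, and what it does not

`generate_record` builds beats as sums of Gaussian bumps (P, Q, R, S, T at
fixed offsets/widths/amplitudes, ~5% per-beat amplitude jitter). PVC beats
suppress the P wave, widen the QRS bumps ×2.5, scale their amplitude ×1.4
(optionally sign-flipped), arrive at 0.7× the nominal RR and are followed
by a pause restoring the 2·RR sum. Normal RR ~ N(0.8 s, 0.04 s); PVCs are
Bernoulli-marked, never adjacent, never first/last. Noise terms: white
Gaussian (0.01 mV), baseline wander (0.05 mV at 0.33 Hz), powerline
(0.01 mV at 50 Hz) — modest levels; detector stress tests raise the white
component explicitly (e.g. to a 10 dB SNR).

`generate_feature_table` samples (pre_RR, post_RR, QRS_area, R_amp)
directly from class-conditional Gaussians with PVC mean shifts of 3.0, 2.2,
1.7 and 1.25 pooled standard deviations respectively — deliberately
overlapping classes (single features are imperfect, pre_RR strongest by
construction) with exact class counts at any requested ratio. A
`separation` scale interpolates to the null model, and `bayes_accuracy`
evaluates the exact Gaussian likelihood-ratio rule as an upper benchmark.

What passing tests on this data do **not** show: real ECG beats are not
Gaussian bumps, real feature distributions are neither Gaussian nor
independent, electrode artifacts and non-PVC arrhythmias are absent, and
the boundary-localizer ground truth uses piecewise-linear flanks because a
smooth bump has no unambiguous onset. Synthetic results validate the
*implementation* (formulas, predicates, counts, calibration), not clinical
performance; the `reproduce-mitbih` harness exists for running the real
study on a locally supplied database copy.

## Problem sizes and determinism

Default experiment sizes were chosen to make sampling noise small relative
to the asserted margins while keeping any single test in the seconds range:
7000-beat tables (13:1), 300-beat records for detector scoring, n = 4000 /
T = 200 for the OOB–holdout comparison, 200 random instances for the split
oracle. Every stochastic component takes an explicit seed
(numpy `default_rng`); fixed seeds reproduce records, tables, balanced
sets, forests and reports byte for byte.

## Known limitations

- Two-class only (PVC vs rest); no S/F/Q sub-classification.
- Single-lead; multi-lead fusion and lead selection beyond "find MLII by
  name" are out of scope.
- WFDB support covers single-segment format-212 records and beat
  annotations (plus a text dialect); formats 16/80/310, multi-segment
  records and rhythm/quality annotations are not parsed.
- The detector's threshold initialization assumes ≥ 2 s of signal; very
  short strips fall back to whatever peaks the learning window provides.
- SMOTE interpolates in feature space and can place synthetic points in
  low-density minority regions; borderline/adaptive variants are not
  implemented.
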