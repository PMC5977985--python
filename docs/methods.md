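# Methods

## Problem and model

The pipeline addresses binary discrimination of subjects who need treatment
for incipient Alzheimer's dementia — progressive MCI and AD, labeled +1 —
from those who do not — cognitively normal and stable MCI, labeled −1 — at
longitudinal time points `m24`, `m18`, `m12` (months before stable
diagnosis) and `t0` (at stable diagnosis). Inputs per subject and time
point are registered 3D volumes (whole-brain plus gray- and white-matter
probability maps; registration and segmentation are assumed done upstream)
and a table of neuropsychological scores.

The classifier is a linear soft-margin SVM in dual form,
y(x) = Σₙ wₙ tₙ k(x, xₙ) + b with k(u, v) = u·v; the stored primal vector
w = Σₙ wₙ tₙ xₙ is verified against the dual expansion at training time.
MRI features are PCA coefficients (or PLS component scores) of the
smoothed, flattened voxel vectors; score features are z-normalized raw
columns. Both streams are ranked by the Fisher discriminant ratio
FDR = (μ_A − μ_B)²/(σ²_A + σ²_B) (a class-separability index, not the
false-discovery rate), with sample variances (n − 1). The wrapper searches
tissue channel × smoothing FWHM × (k_mri, k_np) by inner-loop validation
accuracy inside a stratified fivefold nested cross-validation, refits the
winning configuration on the full outer-training portion, and reports
fold-averaged accuracy, sensitivity (positive class = progressors) and
specificity.

## Key parameters

| parameter | default | notes |
|---|---|---|
| smoothing FWHM grid | {0, 2, 4, 6, 8, 10, 12} mm | 0 = no smoothing; σ = FWHM/(2√(2 ln 2)) per axis in voxel units; reflection boundary |
| PCA components | ≤ n_train − 1 | full rank retained, FDR picks; deterministic sign (largest-\|loading\| entry positive) |
| SVM cost C | 1.0 | not searched by the wrapper (which optimizes only features, channel, FWHM); overridable |
| wrapper k_mri | {1, 2, 5, 10, 20, 50, all} | clamped to available components; for PLS, k_mri is the component count |
| wrapper k_np | {0, 1, 2, 5, 10, 20, 64} | 0 = MRI only |
| folds | 5 outer × 5 inner | 128/32/40 at n = 200; stratified, seed-deterministic |
| permutation iterations | 1000 | reducible for desk-scale runs; p = #{null ≥ observed}/n_iter |
| map threshold | 0.35 | display/reporting cut on the [0, 1]-normalized map |
| predictor cutoff | 0.05 | frequency above which a score is a "best predictor" |

Ties in the inner argmax are broken toward the smaller model: smaller
k_mri, then smaller k_np, then smaller FWHM, then channel order
whole-brain < GM < WM. Decision values exactly 0 classify as +1. A
degenerate (constant) score column z-scores to 0 with a warning; an empty
confusion stratum yields NaN (flagged, never silently 0).

## Design choices where the design was open

* **Per-fold fitting.** PCA/PLS models, FDR rankings and z-score statistics
  are fitted inside each inner training partition only. Fitting them once
  globally would leak test information into selection; the leakage-free
  reading is adopted and enforced by tests (perturbing outer-test subjects
  cannot change a fold's chosen configuration).
* **Separate streams.** PCA applies to voxels only; scores are z-scored and
  FDR-ranked directly. The two blocks are concatenated after ranking, each
  column carrying a provenance label (`mri:<component>` / `np:<score>`).
* **Refit after selection.** The winning configuration is refitted on
  train + validation (160 of 200) before the single test evaluation — the
  standard nested-CV reading.
* **Shared partitions.** The fold partition is a pure function of the seed,
  so runs at different time points, modalities or extractors use matched
  folds, which is what makes the paired fold-level t-tests valid.
* **Permutations rerun everything.** Each permutation iteration reruns
  inner selection, not just the final fit, so the null preserves
  selection-induced optimism. Iteration seeds derive from the master seed
  via a counter. The p-value is the plain ≥-fraction (resolution 1/n_iter,
  can be exactly 0); a smoothed (r+1)/(n+1) variant exists behind a flag.
* **Maps.** The Haufe correction (activation pattern A = Cov(X)·w in the
  trained feature space) is applied per fold before averaging; absolute
  values are averaged so opposing fold signs do not cancel informative
  voxels (a signed per-fold map is available via the library). Min–max
  normalization to [0, 1]; the 35 % threshold is applied only in the
  exported/displayed variant.
* **SVM solver tolerance** is 1e−8 so that dual/primal agreement and the
  symmetry identities hold to the 1e−6 contracts.

## The synthetic generator

`generate_cohort` emulates the target study design: two balanced classes
(default 100 + 100), four time points, three channels on a 20×24×20 grid of
2 mm voxels, 64 scores named after a 7-test battery (FAQ, Clock, AVLT,
Digit Span, category fluency, TMT, BNT). Volumes are Gaussian noise
(sd 1.0), pre-smoothed to 4 mm FWHM to mimic intrinsic spatial smoothness;
the group effect is a mean intensity *decrement* (an atrophy surrogate)
planted in an off-center ellipsoid (~17 % of the grid) of the GM channel
only, growing from 0.30 at `m24` to 0.65 at `t0` so separability increases
toward diagnosis. Eight informative score columns are shifted by d = 0.8
between classes; the rest are pure noise. Everything is reproducible from
one integer seed, and the planted mask/score indices ship in
`bundle.truth`.

What the generator does **not** emulate: brain anatomy, deformation-based
atrophy (the effect is an intensity shift because the pipeline operates on
intensities after segmentation), scanner artifacts, site effects,
covariate structure (age/sex), or subject-level effect heterogeneity.
Because the planted effect is spatially homogeneous and the classifier
aggregates over many voxels, desk-scale cohorts are *much* easier to
classify than clinical data — accuracies here saturate near 1.0, far above
what heterogeneous clinical cohorts allow. Passing tests therefore validate
the machinery (no leakage, correct statistics, recoverable ground truth),
not clinical effect sizes.

## Study sizes used by the drivers, tests and acceptance script

* Wrapper grid for the desk-scale studies: 3 channels × FWHM {0, 4, 8} ×
  k_mri {1, 2, 5, 10} × k_np {0, 2, 5, 10} (the full default grid remains
  the library default).
* Null calibration: one default cohort (n = 200), labels shuffled once;
  chance band = 2·√(0.25/200) ≈ 0.071.
* Permutation p-value uniformity: 200 replicate scores-only null cohorts
  (16 per class, 4×4 nested CV, single grid point, n_iter = 39). The
  cohort is sized so the fold-averaged accuracy has 1/32 grain: with a
  coarser statistic the ≥-fraction p-value is visibly conservative under
  ties, which deflates the type-I rate below its nominal level.
* Signal recovery: five seeds; an MRI-dominant cohort (decrements 1.5–3.0
  sd) for accuracy and importance-map overlap, and a score-dominant cohort
  (decrements 0.1–0.25 sd, score d = 2.2) for predictor-frequency
  recovery. Two cohorts are needed because a saturating MRI effect ties
  every wrapper candidate at accuracy 1, and the tie-break then always
  selects the score-free configuration, leaving the frequency table empty.
* The significance driver runs its permutation demo on a reduced cohort
  (20 per class, 10×12×10 grid) at n_iter = 99.

## Numerical notes

* PCA on wide matrices (features > 2× samples) uses the dual (Gram-matrix)
  eigen-decomposition, algebraically identical to the SVD route and
  verified against it; training scores are cached by the fit.
* PLS follows the deflation scheme (first direction ∝ X_cᵀ y_c); held-out
  projection uses rotations W(PᵀW)⁻¹, whose leading-block consistency makes
  truncation to k components exact. Cross-checked against an independent
  reference implementation.
* FDR with a zero denominator maps to +∞ for a nonzero numerator (a
  zero-variance perfectly separated feature ranks first) and to 0 for 0/0;
  ranking ties keep ascending original index (stable sort).
* Gaussian smoothing uses a unit-sum truncated kernel (truncation at 4σ)
  with reflection boundaries, conserving total intensity to ~1e−6.

## Known limitations

Single-site, balanced, homogeneous-effect cohorts only; no covariate
matching or confound regression; no hyperparameter search over C; no
multi-class setting; anatomical labeling of map clusters is out of scope
(maps are exported as NIfTI for external rendering).
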