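# Methods

## Problem and model

The package predicts a binary molecular label (MGMT promoter methylation:
methylated = positive class) for glioma subjects from co-registered
multiparametric MRI with a three-label tumor subregion mask (enhancing
tumor ET, necrotic core NCR, peritumoral edema ED; BraTS-style integer
codes NCR=1, ED=2, ET=4, remappable). The pipeline is
feature extraction → hybrid feature selection/weighting → SVM evaluation.
Registration, resampling, skull stripping and segmentation are upstream of
the package: inputs are assumed grid-aligned, and masks are consumed as
given.

## Feature bank

Each (sequence, region) pair yields 144 features in nine families
(20 intensity, 61 histogram, 2 volumetric, 19 morphology, 8 GLCM, 10 GLRLM,
18 GLSZM, 5 NGTDM, 1 LBP); over 11 sequences and 3 regions a subject has
4752 features. The family cardinalities are contract; because no single
published list pins down the identities of all 144 features, the exact
definitions are fixed by this package and frozen in
`src/gliorad/data/feature_manifest.json` (checked against the code at test
time). Notable choices:

- **Quantization**: per-ROI min–max binning into B = 16 levels,
  `level(v) = min(B, floor((v − min)/(max − min)·B) + 1)`; a constant ROI
  maps to level 1. B is configurable and tagged in feature names
  (`Bins.16`).
- **GLCM**: counts accumulated over all 13 unique 3D directions at offset
  radius r = 1 into a single matrix, symmetrized (both orderings of each
  pair) and normalized to sum 1. Direction merging gives one value per
  feature, matching the single-name dialect; the per-direction-average
  alternative was rejected to keep the matrix itself well defined.
  Correlation of a single-level ROI is defined as 1 (the degenerate limit).
- **GLRLM**: run-length matrices built per direction (runs broken by
  out-of-ROI voxels), features computed per direction and averaged over the
  13 directions.
- **GLSZM**: zones are 26-connected components of equal level
  (`scipy.ndimage.label`).
- **NGTDM**: Amadasun–King formulation on the cubic 26-neighborhood;
  coarseness of a perfectly flat region is capped at 10^6.
- **LBP**: a single summary — the mean fraction of 26-neighbors whose
  quantized level exceeds the center voxel's.
- **Histogram family (61)**: 32 normalized bin frequencies over the raw
  ROI intensity range plus 29 distribution statistics of the quantized
  levels (entropy, uniformity, moments, deciles, quartiles, dispersion).
- **Shape**: surface area by exposed-voxel-face counting (exactly matches a
  brute-force oracle and keeps sphericity/compactness deterministic);
  principal axis lengths 4·sqrt(eigenvalue) of the physical-coordinate
  covariance; maximum 3D diameter over convex-hull vertices with a
  bounding-box-diagonal guard for pathological hulls.
- **Degenerate ROIs**: where a limit exists it is used (contrast 0 for a
  constant ROI); where not (GLCM of a single voxel), the family becomes a
  NaN sentinel, logged. Strict mode raises instead; permissive mode never
  crashes.

Texture matrices are validated against independent brute-force enumeration
oracles (pair counting, run walking, flood-fill zones, neighborhood
averaging) on random integer volumes up to 4×4×4, and the
direction-aggregated features are checked for invariance under 90°
rotations.

## Hybrid selection and weighting

Within each of `n_folds = 5` stratified, seeded folds the two selectors run
on the training split only:

- **LASSO** (`sklearn.linear_model.Lasso`, α = 0.05) on z-scored features
  against the 0/1 label; nonzero coefficients are selections. Constant
  columns are dropped with a log entry.
- **mRMR**: greedy ranking with F-statistic relevance and
  mean-absolute-Pearson redundancy; the first pick maximizes relevance, each
  next maximizes relevance/redundancy, ties break toward manifest order.
  `mrmr_k = 100` per fold by default (the order of magnitude of a final
  radiomic signature); the mutual-information variant was considered and
  left out to keep a single deterministic formulation.

Each feature accumulates `2.0` per LASSO selection and `1.0` per mRMR
selection (defaults; configurable), so weights live on the lattice
`{2a + b : 0 ≤ a,b ≤ 5}` with maximum 15. The final list is either the
fixed-threshold set (weight ≥ 3.0) or, by default, the set maximizing mean
cross-validated SVM accuracy over the ascending grid of achievable weight
values, ties resolved toward the larger threshold (smaller set). Candidate
sets are nested by construction.

Running selection on training splits only avoids the worst leakage, but the
in-fold metrics that `run_pipeline` reports still reuse folds that informed
the ledger and the threshold choice and are therefore optimistic — on
signal-free data they sit well above chance. `nested_evaluation` refits the
entire procedure (selection, weighting, thresholding, SVM) inside each
outer training split and scores only held-out subjects; this is the
unbiased estimate and the one used for null-calibration checks. A
compatibility flag (`selection_on_full_data`) reproduces the fully leaky
variant for comparison and is off by default.

## Evaluation

ACC = (TP+TN)/(TP+TN+FP+FN) with methylated as the positive class;
sensitivity TP/(TP+FN); specificity TN/(TN+FP); AUC is the rank statistic
P(score⁺ > score⁻) with ties ½, computed per fold from SVM decision scores
and averaged. The SVM is an RBF kernel with C = 1 and feature-count-scaled
gamma, standardized on each training split, no class reweighting by default
(a class-weighted mode exists); kernel and C are configurable since no
single published setting is canonical. Reports carry per-fold values plus
the arithmetic mean, and the family-distribution report gives the
percentage of each feature family before and after selection.

## Synthetic data

The phantom emulates a cohort of subjects with 11 co-registered volumes on
a common grid (default 48³ voxels at 1 mm³) and a three-region mask built
from nested ellipsoids (NCR core within an ET shell within an ED surround)
with per-subject seeded jitter; regions smaller than 8 voxels are rejected
as degenerate. Each volume is a smooth Gaussian-filtered background
(normalized to SD = 2·noise_sd so it dominates the ROI intensity range)
plus weak unsmoothed noise. Class effects are injected per
(sequence, region): a mean shift, and a texture effect that adds
high-frequency noise amplitude for class 1 — raising the ratio of local to
smooth variation, which is what quantized texture features respond to,
without preferring any direction. The default effect profile concentrates
effects in ET on the perfusion maps (DSC-PSR, DSC-rCBV) plus a T1Gd
enhancement shift and a FLAIR edema shift, chosen once as a plausible
perfusion-weighted contrast between methylation classes. Labels follow a
fixed composition, `round(prevalence·n)` positives (default prevalence
97/146), permuted by the seeded stream. One master seed spawns per-subject
substreams, so any subject can be regenerated independently of iteration
order, bit-identically.

The tabular generator plants `n_informative` columns with class-conditional
mean difference `effect_size` on unit-variance noise (optionally
equicorrelated through a shared latent factor) among pure-noise columns;
defaults are n = 200 subjects, 100 features, 5 informative, effect size 3,
balanced classes.

What the phantom does **not** model: registration error, bias fields,
scanner/protocol heterogeneity, realistic tumor geometry or infiltrative
boundaries, or correlated multi-sequence physiology. Passing tests
therefore demonstrate correctness of the computations and recoverability of
planted signal under clean conditions — not clinical performance on real
cohorts, which additionally depends on all of the above.

## Numerical and design notes

- All randomness flows from integer seeds through `numpy.random.Generator`
  (`SeedSequence` spawn keys for substreams); identical inputs and seeds
  give identical outputs, including byte-identical result JSONs.
- Tie-breaks everywhere (mRMR, threshold search, mode of a histogram) go to
  the earlier manifest/column position or the larger threshold, making runs
  reproducible.
- Feature tables are written with 12 significant digits; round trips are
  lossless at that precision.
- Problem sizes in the test suite and acceptance script (grid 24–48
  phantoms, cohorts of 12–40, tabular 200×100, 10–20 seeds per
  simulation check) were chosen so the full suite runs in about a minute on
  one CPU while keeping the simulation checks statistically meaningful.

## Known limitations

- The 144-feature identities are this package's frozen convention; other
  radiomics tools will produce differently defined (if similarly named)
  values, so absolute feature values are not interchangeable across
  packages.
- The threshold search optimizes in-sample CV accuracy; its reported
  accuracy must be read as optimistic. Use `nested_evaluation` when an
  honest number is needed.
- mRMR with `mrmr_k` ≥ the feature count degenerates to "select all",
  leaving LASSO as the only discriminating selector; with the 4752-feature
  imaging matrix the default `mrmr_k = 100` is genuinely selective.
- Single-voxel or constant regions produce NaN sentinels for texture
  families in permissive mode; downstream selection requires complete
  columns, so such features must be imputed or dropped by the caller.
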