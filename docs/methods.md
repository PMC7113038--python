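# Methods

This note documents the models, numerical choices and limitations of the
`radpdl1` pipeline in the order data flows through it.

## Feature extraction (the 58-feature catalogue)

All features are computed inside the binary tumor mask of a 3-D HU volume
with per-axis voxel spacing in mm; voxel indices are 0-based and every
physical quantity is in mm/mm²/mm³, so nothing depends silently on scanner
geometry.

**Discretization.** Texture features use equal-width binning of the
in-mask HU range into `G` levels (default 32, configurable). Bins are
half-open on the right, the maximum maps to level `G`, and a constant VOI
yields a flagged single-level result. The default of 32 was chosen because
co-occurrence magnitudes at a few dozen levels match the scale of texture
values a practitioner expects from commercial tools (e.g. autocorrelation
of order 10³ at 32 levels). Min–max binning makes texture scale-free but
sensitive to in-mask intensity extremes; this matters for the phantom
design below.

**Histogram (15).** Mean, SD (sample, ddof=1), skewness and excess
kurtosis (standardized moments; defined 0 with a flag for constant input),
min, max, voxel count, and percentiles 10/25/50/75/90/95 with linear
interpolation between order statistics, all on raw HU. Energy = Σpᵢ² and
Entropy = −Σpᵢlog₂pᵢ are computed on the G-level discretized histogram,
making them independent of the HU scale.

**Gradient (2).** Mean and SD of the 3-D gradient magnitude in HU/mm.
Derivatives are finite differences between in-mask voxels only (central
where both axis neighbours are in the mask, one-sided where one is, zero
otherwise), so the tumor/lung edge never leaks into the statistics and a
constant VOI has exactly zero gradient.

**GLCM (13).** Co-occurrence counts are accumulated over the 13 unique
distance-1 offsets of the 26-neighbourhood, symmetrized, pooled across
directions, and normalized. Features: ASM, IDM (squared-difference
kernel), Homogeneity (absolute-difference kernel — the catalogue lists
both, so the two kernels disambiguate them), Contrast, Correlation
(defined 0 with a flag at zero marginal variance), Autocorrelation,
Entropy (log₂), cluster prominence/shade/tendency (4th/3rd/2nd powers of
i+j−2μ), SumEntropy on p_{x+y}, DiffAverage and DiffEntropy on p_{|i−j|}.

**GLRLM (13).** Run-length matrices are computed per direction (runs of
equal level along the offset, broken by the mask) and the 13 per-direction
feature values are averaged. Standard normalizations are used: SRE/LRE/
LGRE/HGRE and the four cross terms divide by the number of runs, GNUN and
RLNUN by its square, RP = runs/voxels, RV is the run-length variance under
the run distribution, RE the run entropy (log₂). The commercial tool
behind the emulated analysis prints run statistics on visibly different
scales (its normalization is unpublished); numeric parity with those
printed magnitudes is explicitly not a goal — directions of group
differences are.

**Moments (3).** J1, J2, J3 are the trace, sum of principal 2×2 minors and
determinant of the intensity-weighted, weight-normalized central
second-moment matrix of in-mask voxel positions in mm — the three rotation
invariants of that matrix. Weights are the HU values; if any weight would
be ≤ 0 the intensities are shifted to I − min + 1 HU (flagged).

**Shape (11).** Volume = voxel count × voxel volume. Surface area is a
marching-cubes isosurface at level 0.5 after a 0.6-voxel Gaussian
anti-aliasing of the mask (the raw staircase overestimates a sphere's area
by ~8%; the smoothed surface is within ~2%, verified against the closed
form). Sphericity = π^⅓(6V)^⅔/A and Compactness = 36πV²/A³, both 1 for an
ideal sphere. Roundness = geometric mean of the three PCA SDs over the
largest (a dimensionless isotropy in [0,1]). Circularity = 4πA_s/P² of the
largest cross-section searched over all three axis-aligned stacks, with a
sub-pixel contour perimeter; searching all three stacks (not only the
conventional axial one) keeps the feature invariant under grid rotations.
Longest1stAxis is the maximal pairwise distance between boundary voxels
(via the convex hull); Longest2ndAxis the same after projecting out the
first direction. PCA SDs are the root eigenvalues of the mask-voxel
coordinate covariance in mm.

**Fractal (1).** Box-counting dimension of the boundary voxel set
(mask minus its 6-connected erosion). Counts are taken on dyadic scales
from {1,2,4,8,16}, restricted to the three finest scales not exceeding
half the bounding box — at coarser scales the count saturates on the
bounding box and the slope is biased toward 3. The count at each scale is
averaged over the 8 corner anchorings of the box grid, which makes it
exactly invariant under axis flips and permutations; anchoring to the
mask's bounding box makes it translation-invariant. The dimension is the
least-squares slope of log N(s) vs log(1/s), clipped to [0,3]. Verified:
≈2 for a solid cube's boundary, ≈1 for a voxel line.

**Invariances.** All 58 features are invariant under 90° grid rotations
and translations of isotropic-spacing inputs (tolerance 1e-6, relative
above magnitude 1); orientation-sensitive numerics (marching cubes) run on
a canonical representative of the mask's symmetry orbit to make this exact
rather than approximate. GLCM matrices are symmetric and normalized, and
GLRLM runs conserve the voxel count per direction, on every input; both
texture families match independent brute-force implementations to 1e-10.

## Synthetic phantoms

The generator's purpose is statistical, not anatomical: it produces
cohorts on which every downstream stage behaves the way the emulated
clinical analysis assumes.

One tumor = a lobulated ellipsoid (semi-axes ~13/11/9 mm, radial
perturbation by a low-order random spherical function, amplitude 0.12 of
the radius) at the center of a 32³ grid of 1.5 mm voxels, filled with a
stationary Gaussian random field (smoothed white noise; correlation length
2.2 mm, SD 60 HU around a 40 HU base), on a −800 HU lung-like background
with 15 HU white noise. Heterogeneity comes from two components: an
optional smooth-edged necrotic core (probability 0.5, −150 HU) and
optional air-bronchogram-like foci (per-tumor presence probability 0.25;
when present, 1% of voxels at −600 HU).

**The planted label effect** (scaled by `effect_homogeneity`, default 1):
positive tumors draw a 1.45× longer texture correlation length, a 5×
lower necrosis probability, and an air-focus presence probability of 0.60
instead of 0.25. The deep foci are the load-bearing component: under
min–max binning they stretch the in-mask range, compressing the solid
bulk into fewer, higher gray levels — which simultaneously raises ASM and
the high-gray run statistics (HGRE, SRHGE) and the run-length variance in
the positive group, the direction pattern the analysis is designed to
detect. (A bright-speckle mechanism fails here: stretching the *max* pushes
the bulk to *lower* levels.) Effect sizes are calibrated at d ≈ 0.4–0.8
per feature, slightly stronger than the real-data effects so that recovery
is reliable at n=153, and deliberately not a multivariately perfect
separation (Rad-score AUC ≈ 0.84 rather than ≈ 1): subject-level
variability in size, base attenuation, texture scale and correlation
length (log-normal jitter, e.g. σ=0.30 on correlation length) dominates
any single feature. With `effect_homogeneity=0` the two label groups are
distribution-identical. One planted direction is knowingly not reproduced:
run entropy comes out slightly *lower* in positives under the standard
definition, opposite to the printed clinical table — a consequence of
using standard GLRLM normalizations.

**Cohort structure.** Labels are Bernoulli(53/153); age (64.6 ± 10.7 y),
sex (65% male), smoking (current/past/never = 27/59/67 per 153) and EGFR
status (33% mutant) are drawn independently of the label, so the clinical
model is null by construction. Every subject gets a second reader's mask:
a smooth random surface perturbation of amplitude 0.8 mm (signed-distance
threshold against a correlated Gaussian field), with newly added voxels
kept only if tumor-like in intensity (> −550 HU) — a reader delineating on
the image does not include clear lung. This yields the near-1 ICCs of real
two-reader radiomics; pushing the amplitude to ~3 mm drives surface-based
features below the 0.75 ICC threshold, emulating the fragile-feature
phenomenon.

**What the phantoms do not model** (so what green tests do not show):
anatomy (vessels, bronchi, pleura), scanner/kernel effects, partial-volume
edges, contrast dynamics, and the true covariance of clinical radiomic
features. A pipeline that recovers planted effects here is verified as
software; nothing about real-cohort effect sizes follows.

## Selection, signature, cutoff

Step 1 keeps features with two-reader ICC(2,1) — two-way random effects,
absolute agreement, single measure, from ANOVA mean squares — strictly
above 0.75; negative ICCs are treated as 0 (raw values are also reported),
and the top is clipped at 1 to absorb float noise. The consistency form
ICC(3,1) is available for sensitivity analysis. Weighted kappa (for
ordinal visual readings) uses linear weights by default; both choices are
configurable because the emulated analysis named neither.

Step 2 is a pooled-variance two-sample *t*-test per feature (Welch
optional), retaining p < 0.05 with no multiplicity correction — matching
the emulated procedure; expect ~3 false survivors from 58 nulls.

Step 3 standardizes the surviving features (z-scores), builds a penalty
grid of 100 log-spaced values from the data-derived λ_max (the smallest
penalty that zeroes all coefficients) down by 1e-4, and for each penalty
measures the validation AUC in every fold of `repeats` (default 100)
stratified 3-fold splits. The chosen λ maximizes the mean per-fold AUC,
ties broken toward the sparser model. The path is computed per training
fold with a warm-started SAGA solver (tolerance 1e-4 — the AUC curve is
insensitive at this precision); the final model is refit on all data with
liblinear at tolerance 1e-8. Coefficients are reported on the raw feature
scale (β_raw = β_std/σ, intercept adjusted), which reproduces the
standardized-scale per-subject scores to 1e-10 and matches how the
published signature prints its coefficients. "Mean AUC" averages over all
folds of all repetitions; averaging repetitions of pooled-fold AUC is the
other defensible reading and is not implemented.

The Rad-score is the linear signature evaluated on raw features. The
classification cutoff maximizes the Youden index over midpoints between
consecutive distinct scores, computed in integer arithmetic (tp·n₀ + tn·n₁)
so ties are exact; ties break toward the higher cutoff (higher
specificity), and positivity is strict (score > cutoff), so a score exactly
at the cutoff is negative. Age is dichotomized as age ≤ cutoff with the
cutoff Youden-derived by default (configurable to a fixed value).

## Models and validation

Logistic fits are maximum likelihood (statsmodels) with Wald ORs and 95%
CIs; reference levels are male, never-smoker, EGFR wild-type, age above
the cutoff. On separation or a singular design the point estimate falls
back to a faintly ridged fit (C=1e4) with CIs suppressed and a flag. The
c-statistic of a model is the midrank concordance AUC of its linear
predictor, with a DeLong CI.

Two nested models are compared: clinical only, and clinical + dichotomized
Rad-score. The difference in c-statistics gets the paired DeLong test
(structural components; p = 1 by convention at degenerate variance).
Internal validation follows the resample–refit optimism scheme: for each
of B (default 1000) stratified bootstrap resamples both models are refit,
optimism = (apparent c on the resample) − (that refit's c on the original
data), and corrected c = full-data apparent c − mean optimism; the
between-model difference takes a percentile 95% CI over the resample
deltas. Resampling is stratified by label to avoid single-class resamples
(plain bootstrap with redraws is available). Bootstrap refits use the
faint-ridge solver throughout, since resamples routinely separate.

## Determinism and problem sizes

Every stochastic component is a pure function of an integer seed: phantom
and cohort generation, CV fold assignment (seeds spawned from a
SeedSequence), and bootstrap resampling. Re-running any stage with the
same config and seed reproduces every number bit-for-bit.

Defaults follow the emulated analysis (G=32, ICC > 0.75, α=0.05, 3 folds ×
100 repeats, B=1000). The test suite and the acceptance script run smaller
problems chosen to keep a full run in minutes on one CPU: 24³–32³ phantom
grids, cohorts of 36–153 subjects, 2–10 CV repetitions, B=30–500. The
selection-recovery check uses 20 seeded cohorts at n=153 and tests that
the univariate screen retains the strongest planted features and that the
sparse signature contains planted-family texture features; an L1 signature
legitimately keeps only a subset of a correlated block, so membership is
asserted at the family level.

## Known limitations

- Feature definitions follow standard conventions, not the unpublished
  vendor formulas of the emulated analysis; printed clinical magnitudes
  (especially GLRLM and Compactness) are not comparable numerically.
- Min–max discretization ties texture values to in-mask extremes; a single
  deep or bright voxel shifts all level-based features. This is faithful
  to the stated binning rule but is why the reader-2 mask gates added
  voxels by intensity.
- The univariate screen inherits the emulated analysis's lack of
  multiplicity control; the LASSO step prunes most false survivors but the
  reported CV AUC at the chosen penalty is still an optimistic estimate
  (no nested CV): on effect-free cohorts it sits well above 0.5 because the
  screen ran on the full data first.
- The bootstrap optimism correction refits the logistic models per
  resample but holds the signature — itself selected on the same data —
  fixed, so the corrected between-model Δc remains positive even under the
  null. Honest null calibration therefore requires independent data, which
  is how the test suite measures it (signature AUC ≈ 0.5 and Δc ≈ 0 on a
  fresh effect-free cohort).
- Phantom cohorts have cleaner covariance structure than clinical data;
  selection frequencies and c-indices on them bound software correctness,
  not clinical performance.
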