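# Methods

This note documents the models, conventions and numerical choices
behind `radsig`, in the order the pipeline runs.

## Synthetic phantom cohorts

`radsig.phantom` renders per-subject pairs of co-registered volumes on
one grid (default 32 × 32 × 16 voxels at 1 × 1 × 2 mm, deliberately
anisotropic so resampling is always exercised):

* **MR-like image**: an ellipsoidal soft-tissue body (level ≈ 100) with
  an ellipsoidal tumour (GTV) whose interior carries a stationary
  Gaussian random field — white noise smoothed with a Gaussian kernel
  of the configured correlation length (default 2 mm) and rescaled to
  unit variance, so one knob controls heterogeneity and texture
  features respond to it monotonically. The whole image is multiplied
  by a smooth random low-order polynomial bias field normalised to
  [1 − a, 1 + a] (default a = 0.2), a small constant background offset
  (default 2) emulates residual background signal outside the body, and
  Gaussian noise (default SD 2) is added.
* **CT-like image**: air (−1000 HU) outside the body, soft tissue
  around 40 HU inside, all soft-tissue voxels clipped into
  [−150, 180] HU so the re-segmentation window is exact; configurable
  fractions of in-GTV voxels are replaced by air-like (−800 to −300 HU)
  and bone-like (400 to 1000 HU) values with exact rounded counts.

Cohorts add per-subject anatomical variability — tumour radius
uniform in ±40% of nominal, tissue level ±15%, tumour/tissue contrast
1.2–1.7, texture amplitude 0.7–1.5×, CT soft-tissue level 20–60 HU.
These ranges were chosen so that between-subject feature variance
dominates the within-subject variance induced by the robustness
perturbations, as it does in patient cohorts where tumour volumes span
orders of magnitude; without them every feature would fail the ICC
screen by construction.

Outcomes follow a logistic (binary response) or exponential
proportional-hazards (survival, with independent exponential censoring)
model on a latent image property — the in-GTV MR maximum (driven by a
variable Gaussian hotspot) or the in-GTV standard deviation. The
property is *measured from the rendered image* and standardised across
the cohort before the outcome draw, so parameter-recovery tests compare
against the exact generating coefficient with no rendering
approximation. Degenerate all-one-class draws are retried with an
incremented stream (at most 100 times). Clinical covariates (a 3-level
stage factor) are drawn independently unless an effect is configured.

The tabular generator (`generate_feature_cohort`) draws multivariate
normal features with block-wise equicorrelation (Cholesky; a
non-positive-definite block raises, naming the block) and the same
outcome models on planted columns; columns reuse real catalogue names.

## Preprocessing

* **Soft-tissue mask**: slice-wise Canny edges (σ = 1.5; low/high
  thresholds 0.05/0.10 of the global 99.5th-percentile intensity, so
  empty slices yield no spurious edges), closed by dilation, hole-filled
  and eroded back, then the largest 3D connected component. Multiplying
  with the mask sets the background to exactly zero.
* **Bias correction**: a robust least-squares polynomial (order 2) fit
  to the log intensities inside the body mask, with one
  Huber-style reweighting pass so focal anatomy does not masquerade as
  bias; the exponentiated fit is divided out and the in-mask mean is
  restored exactly. Any callable `(image, mask, config) -> field` can
  replace the default estimator (e.g. an external N4 implementation).
  Non-positive in-mask values are shifted by a logged epsilon before
  the log transform.
* **Percentile scaling** divides by the in-body-mask 95th percentile
  (linear-interpolation quantile). Values above the divisor are kept,
  not clipped — clipping would destroy the maximum-intensity
  information that intensity extrema features carry.
* **Resampling**: trilinear interpolation onto the 1 mm isotropic grid
  covering the original extent, origin conserved; masks are
  interpolated then thresholded at 0.5 (ties foreground). Trilinear
  interpolation is exact on affine intensity fields, which the tests
  exploit.
* **Re-segmentation** keeps CT ROI voxels inside [−150, 180] HU (bounds
  inclusive). The re-segmented mask feeds intensity, histogram and
  texture features; morphology uses the original delineation.
* **LoG filter bank**: separable convolution with per-axis sampled
  Gaussian and second-derivative kernels (σ converted from mm to voxels
  per axis, mirror padding). The second-derivative kernels are
  corrected to sum exactly to zero, so constants map to exactly zero
  response and the filter is strictly linear. Kernels are *not*
  scale-normalised (plain LoG). The five response maps (1–5 mm) are
  averaged voxel-wise into a single map.

Order contract: MR = mask → bias-correct → scale → resample → LoG;
CT = resample → re-segment → LoG (the filter sees the full image).

## Feature catalogue

The catalogue (`radsig.features.catalogue`) is the single source of
truth for names and counts: 25 morphology, 25 intensity statistics,
32 intensity-histogram, 95 texture (GLCM 25, GLRLM 16, GLSZM 16,
GLDZM 16, NGTDM 5, NGLDM 17), and the 57 first-order features repeated
on the LoG map — 234 per modality. Morphology is the standard 29-item
reference list minus the four oriented-bounding-box / minimum-volume
ellipsoid densities. The first-order lists extend the usual 18
statistics / 23 histogram features with additional quantiles and
summaries (p5, p25, p75, p95, SD, sum, 10%-trimmed mean, occupied-level
count, gradient range) to the catalogue size of 57; membership is
enforced by tests, names follow the
`<MOD>[_log]_<family>_<feature>[_d1][_3d[_v_mrg]][_fbn_n32]` pattern.

Conventions: population (ddof = 0) moments and excess kurtosis;
linear-interpolation quantiles everywhere; entropies in bits;
discretisation is fixed-bin-number with 32 bins,
`level = min(floor(K·(x−min)/(max−min)) + 1, K)`, constant ROIs map to
level 1. Texture matrices are built in 3D with Chebyshev distance 1
(13 direction pairs); GLCM and GLRLM merge the per-direction matrices
before computing features; GLSZM/GLDZM zones are 26-connected; GLDZM
distances are city-block distances to the morphological ROI edge (edge
voxels = 1, zones outside the morphological mask floor at 1); the NGLDM
dependence count is 1 + the number of neighbours with an identical
level (α = 0), so counts start at 1 and the dependence-count percentage
is 1 by construction (the constant column is removed later by the
variance screens). Degenerate denominators (zero variance,
single-level matrices, ROIs with < 2 voxels) return 0 so feature
tables stay finite; ROIs with < 8 voxels use voxel-counting
approximations for morphology, flagged.

Mesh morphology uses marching cubes on the 0.5 isosurface of the
mildly smoothed (σ = 0.8 voxels) zero-padded mask — the smoothing
removes the staircase bias that otherwise inflates the surface area of
a voxelised ball by ~8%; maximum 3D diameter is computed on the convex
hull of the mesh vertices. Moran's I and Geary's C use inverse-distance
weights over all voxel-centre pairs; above 800 ROI voxels a
deterministic every-k-th subsample keeps the quadratic sum tractable.

## Robustness

The perturbation factorial is volume changes {0, −15%, +15%} × per-axis
translations {0, 0.25, 0.75 mm} = 81 settings, each with its own
deterministic noise seed (noise is drawn fresh in every combination,
matching the 81-variant count rather than acting as a fourth factor).
Noise SD is estimated per image as a robust SD (1.4826 × the median
absolute deviation) of the 6-connected discrete Laplacian divided by
√42 (its noise gain), inside a flat-region mask (the body mask when
available; otherwise voxels above −500 HU for CT, or non-zero voxels
for background-masked MR, eroded by two voxels). Smooth structure is
annihilated by the Laplacian and the sparse strong responses of tissue
interfaces are suppressed by the MAD, so neither ramps nor air/body
edges inflate the estimate.
Volume adaptation thresholds a signed Euclidean distance map (smoothed
with σ = 0.7 voxels to break whole-shell ties) with bisection to within
2% of the target count. Translation resamples the image content
trilinearly against a fixed mask, emulating positioning uncertainty;
the LoG maps and the CT re-segmentation are recomputed per variant.

ICC is the one-way random-effects single-measurement form ICC(1,1) —
perturbed variants are not meaningful "raters" — with the exact
F-distribution two-sided 95% CI; a feature is kept iff the lower bound
is ≥ 0.8. Zero-variance features are removed and flagged.

## Redundancy and discovery

Spearman correlation uses mid-rank ties; clustering is average-linkage
agglomeration on 1 − |ρ| cut at 0.2 (|ρ| rather than signed ρ:
anti-correlated duplicates are equally redundant for modelling).
Mutual information uses equal-frequency 4-bin discretisation of the
feature (nats); the survival endpoint enters through its event
indicator.

The CV scheme stratifies by label or event indicator (scikit-learn
stratified folds: per-fold class counts differ by at most one).
Yeo–Johnson λ is found by bounded profile-likelihood search in
[−5, 5]; transform parameters and z-scaling are always frozen on the
internal training part. Selectors: MIM = top-k MI; MRMR = greedy
difference criterion (relevance MI − mean redundancy MI against the
selected set) with the same MI estimator; elastic net = mixing 0.5,
12-point geometric λ path, penalty weight chosen by internal
5-fold CV (held-out deviance for logistic via saga with warm starts;
held-out concordance for Cox via the glmnet-style coordinate-descent
path in scikit-survival), members ranked by |coefficient|;
univariable = smallest Wald p from dedicated Newton fitters (logistic;
Cox with Efron ties). Occurrence denominators are always the full run
count even when a selector returns an empty list; "75% of 4 methods"
means at least 3; cumulative-occurrence ties break lexicographically.

## Models and evaluation

Logistic fits use Newton maximum likelihood (statsmodels, tolerance
1e−8); non-convergence or runaway coefficients raise, naming the
covariate. Cox fits use lifelines (Efron ties); predicted survival
comes from the Breslow baseline cumulative hazard. AUC is the
Mann–Whitney statistic with ties counted 1/2; Harrell's C counts a pair
as usable when the shorter time is an event (ties in score count 1/2).
Bootstrap CIs are bias-corrected and accelerated (jackknife
acceleration; BC-only is switchable) over 400 resamples; one-class
resamples are redrawn and logged. The Youden cutoff scans midpoints of
adjacent observed scores (ties toward the lower threshold, predictions
are positive at score ≥ threshold); the maxstat cutoff maximises the
absolute standardized two-sample log-rank statistic over midpoints with
both groups ≥ 10% of subjects. Hosmer–Lemeshow uses equal-frequency
deciles (duplicate quantile edges collapse groups; df = groups − 2,
minimum 1). The GND test compares the per-group Kaplan–Meier survival
at the landmark time (default 24 months in the pipeline, configurable;
the examples use 12) with the mean predicted survival, standardized by
the Greenwood variance; groups with zero variance are dropped and the
df equals the number of contributing groups. All tests are two-sided at
α = 0.05.

## Problem sizes and what the tests show

The suite runs phantom imaging stages on 16³–32³ grids with GTV radii
of 3–8 mm and cohorts of 6–20 subjects, robustness on reduced
perturbation grids where only combinatorics are not at stake, and the
modelling stages on tabular cohorts of n = 100–2000 with 3–50 features;
these sizes make the full suite and the acceptance script complete on a
single CPU in minutes while still leaving every rule (81 variants, 99
runs, occurrence thresholds) at its real value. Passing tests show the
machinery is correct against brute-force oracles and that planted
signals of realistic strength are recovered; they do not show that the
phantom reproduces patient-image feature distributions — scanner-
specific noise, anatomy, delineation variability and inter-site effects
are out of scope by design.

## Known limitations

* The bias-field corrector is a contract-level stand-in for dedicated
  histogram-sharpening correctors; it restores low-order multiplicative
  fields exactly but not high-frequency coil patterns.
* GLDZM distances use the city-block metric on the voxel grid;
  anisotropic spacing is not folded into the distance (distances are in
  voxel steps, as is conventional after isotropic resampling).
* The NGLDM dependence-count convention (count ≥ 1) and the extended
  first-order lists are catalogue choices; both are documented above
  and pinned by tests rather than by an external registry.
* Rigid inter-modality registration, DICOM handling and 2D extraction
  are out of scope; masks are assumed co-registered per modality.
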