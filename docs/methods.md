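# Methods

This note documents the models, conventions, and design choices behind
`radiomath`, in the package's own terms.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Synthetic cohort

The cohort generator emulates a sample of 77 children in grades 3–6
(group sizes 24/24/17/12) with four WJ-III mathematics scores —
Math fluency (160 items), Calculation (46), Applied problems (62),
Quantitative concepts (57) — whose per-grade means and SDs and whose
age-partialled inter-test correlations (0.34–0.69) match the study
cohort's published descriptors.

Model.  Within grade *g*, age is uniform on a band whose mean and SD
match the grade's descriptors (half-width = SD·√3); raw score for test
*t* is `μ_tg + σ_tg · z_t`, with `z ~ N(0, R*)`, rounded to an integer
(scores are item counts) and clipped to the item maximum.  Sex is
generated (for table realism) but drives nothing — the study found no
sex effect, and no downstream stage consumes it.

Latent-correlation calibration.  The user-facing correlation target is
the *age-partialled* matrix.  Pooling grades whose score means are not
collinear with their age means leaves a grade-mean residual after the
linear age regression, which adds common positive covariance across
tests; within-grade age jitter times the regression slope and the
integer-rounding variance (1/12) also enter the residual moments.
Setting the latent `R*` equal to the partial-correlation target
therefore misses some pairs by up to ~0.03.  Instead `R*` is solved
from the target analytically:

    partial_ts = (E[σ_t σ_s]·R*_ts + c_ts) / sqrt(V_t V_s)

with `V_t = E[σ_t²] + Var_g(r_t) + b_t²·E[Var(age|g)] + 1/12` and
`c_ts` the grade-residual covariance — every term computable from the
spec before any data are drawn.  The result is projected to the
nearest positive-semidefinite correlation matrix if needed (the
default calibration needs no projection).  `tests/test_acceptance.py`
verifies recovery of the printed grade-3 Math fluency mean, the
weighted whole-cohort mean, and the 0.386 fluency–calculation partial
correlation at n = 10⁵ (±0.02).

## Synthetic phantoms

A phantom stands in for a parcellated structural volume: K disjoint
axis-aligned ellipsoids (default K = 12 on a 64³ grid at 1 mm isotropic
spacing; anatomy is deliberately absent because downstream stages
consume statistical structure only).  Each ROI is filled with
`base + σ·field`, where `field` is white noise smoothed with a
Gaussian kernel (default σ_smooth = 1 voxel — the spatial correlation
gives the texture matrices something non-trivial to measure) and
standardized volume-wide, over a dimmer noisy background.  Defaults:
base intensity 300, noise SD 50, background 100/20; with bin width 25
this yields roughly 8–14 gray levels per ROI.

Signal plan.  A planted effect ties one ROI property multiplicatively
to a subject's normalized score s ∈ [0, 1] with effect size β:
texture-contrast scales the noise SD by (1 + βs), volume scales the
ellipsoid volume, mean-intensity scales the base level.  With all
β = 0, ROI samples are exchangeable across subjects (verified by a
two-sample KS test at nominal rate on unsmoothed phantoms, where the
KS independence assumption holds exactly).

The published study gives no effect sizes linking image features to
scores; the β used by the power checks (β = 3 on texture contrast) is
a property of the test suite, chosen so a strong, unambiguous signal
exists — it estimates nothing about real brains.

## Feature catalog

Exactly 100 features per ROI: 14 shape, 18 first-order, 22 GLCM,
16 GLRLM, 16 GLSZM, 14 GLDM — the standard enabled sets of widely used
radiomics engines, with no NGTDM family.  The study names its feature
count but its itemized list is not deposited; this catalog is the
declared stand-in, and its identity and order are frozen in
`radiomath.catalog`.  For importance reporting, volume =
{MeshVolume, VoxelVolume} is split from the remaining 12 shape
features; first-order features are "intensity"; the 68 matrix features
are "texture".

Conventions (shared by the vectorized implementation and the
brute-force reference in `tests/_reference.py`, which re-derives every
value from the textbook formula with plain loops):

* Discretization: `bin = ⌊(x − ROI min)/w⌋ + 1`, w = 25, applied after
  histogram matching; N_g = max bin; unoccupied intermediate levels
  keep their row in the matrices.
* Logs are base 2 with 0·log 0 := 0; no epsilon terms anywhere.
* Percentiles interpolate linearly between order statistics; moments
  are population moments; Kurtosis is not Fisher-corrected.
* Degenerate ROIs stay finite by convention: zero-variance ROIs take
  Skewness = Kurtosis = 0, GLCM Correlation = 1 and Imc1 = 0; a
  single-voxel ROI contributes a single-cell GLCM of probability 1.
* GLCM/GLRLM use the 13 unique 3D unit-offset directions at distance
  1; GLCM matrices are symmetric and normalized per direction;
  features are averaged over directions with valid pairs.
* GLSZM zones are 26-connected equal-level components; GLDM dependence
  uses gray-level tolerance 0, and the matrix column is the dependence
  *size* (the voxel plus its dependent 26-neighbours, so j ≥ 1 and the
  1/j² small-dependence weights are finite).
* Shape: surface quantities come from a marching-cubes mesh of the
  binary mask at level 0.5 (binary meshes overestimate curved
  surfaces slightly, so a digital ball's sphericity plateaus near
  0.93 — tested as such, not as 1.0).  Axis lengths use the principal
  components of physical voxel centres plus a `spacing²/12`
  within-voxel variance term: a continuous-voxel model that makes a
  1×1×10 line score Elongation exactly 0.1 and keeps single-voxel
  ROIs isotropic.  Maximum diameters are voxel-centre pairwise
  distances (restricted per array axis for the three 2D variants),
  computed on boundary voxels only — the maxima are attained there.

Intensity standardization is whole-volume histogram matching to a
configurable reference subject (`scikit-image`'s quantile mapping).
Bias-field correction, registration, and the parcellation itself are
out of scope: the pipeline consumes native-space label maps.

## Ranking protocol

Per area and test: 20 random 80/20 subject-level partitions (no
stratification); per partition, sequential correlation-based selection
(ρ² > 0.8, catalog order, fitted on the training split only — a
`global` scope fitted once on all subjects is available, since the
study's reporting of one retention per area admits either reading);
then 100 random forests (100 trees, depth ≤ 5, variance-reduction
splits, bootstrap bagging) with seeds derived from (master seed,
partition, model) via `numpy.random.SeedSequence`.  Partition error is
the mean of the models' hold-out MAEs; the area's error is the median
over partitions; ties in the final ordering break by ROI label.  MAE
(not MSE) is used throughout for robustness to outliers.  Scores enter
as per-test min–max normalized values over the analysis cohort — the
transform behind MAEs on the ~0.1–0.25 scale — with the constants
recorded in the run manifest.

The 100 models of a partition differ only by forest seed; selection
and splits are shared within the partition.

## Significance

Two flags are reported side by side, since the study's two two-sigma
thresholds (across areas, and versus noise) admit joint or sequential
readings:

* **relevant**: MAE < mean − 2·SD across areas (sample SD, ddof = 1);
  the nominal lower-tail probability Φ(−2) = 0.02275 truncates to the
  0.022 quoted with the rule.
* **significant**: z = (MAE − μ_noise)/σ_noise < −2 against a noise
  distribution built by re-running the *identical* protocol — same
  partitions, same model seeds — on i.i.d. N(0, 1) feature matrices
  whose dimensionality matches the median post-selection feature count
  across areas, plus age.  Conditioning the replicates on the same
  partitions as the areas removes split-to-split variance the areas
  never see and centres the null correctly.

p-values come from a normal fit to the replicate MAEs: meaningful area
z-scores land far below any empirical-rank resolution (an empirical
rank option exists).  At least 30 replicates are required; 100 is the
default outside the simulation suites.  No multiple-testing correction
is applied — the hypotheses are per-area by design.

Known limitation — the null is anticonservative.  The i.i.d.-noise
null matches the *count* of a typical post-selection feature set but
not its correlation structure or marginals.  Real radiomics features
are mutually correlated and partly heavy-tailed, so null areas show
more between-area spread in chance score alignment than noise
replicates do; their z-scores come out over-dispersed and the z < −2
flag fires somewhat more often than the nominal 2.3% (the calibration
check in `tests/test_acceptance.py` measures the realized rate on
all-noise phantoms and asserts the nominal band — it documents this
excess rather than hiding it).  No i.i.d. feature dimensionality
removes the mismatch: matching the full input width instead of the
post-selection count inflates μ_noise (more junk features, more
overfitting) and makes things worse.  The effect grows with ROI size,
as smoother feature estimates strengthen inter-feature correlation.
This anticonservatism is inherent to count-matched i.i.d.-noise
randomization nulls applied to correlated feature sets — a property of
the method, not of this implementation — and p-values near the
threshold should be read accordingly.

## Importance decomposition

Per area, Gini importances are averaged over all fitted models
(20 × 100 under the full protocol), with features absent from a
partition's kept set contributing 0 — this keeps family shares
comparable across partitions with different kept sets.  Family sums
over {age, volume, shape, intensity, texture} are rescaled to 100%.
Stability: the across-model SD of each feature's importance is
compared against mean + 2·SD (population) of all SDs; exceeders are
flagged as variability outliers.  "Across models" was chosen over
across-partitions or across-areas as the finest aggregation level; the
flag definition is a parameter of `flag_unstable`.

## Problem sizes

The full protocol (20 partitions × 100 models × 100 trees, K = 191
areas) is the configured default (`protocol="paper"`).  The simulation
studies and the demo profile run a structurally identical scaled-down
protocol — 5 partitions × 2 models × 10 trees, K = 12 ellipsoids of
radius 3.2 voxels on a 28³ grid, 30 noise replicates — sized so the
whole statistical battery (40 null seeds + 20 signal seeds × 77
subjects × 12 ROIs) runs in minutes on one core.  Calibration and
power are properties of the distributional match between areas and
noise replicates, which the scaled protocol preserves because both
sides use the identical configuration.

## What passing tests do and do not show

The phantoms share the cohort's score structure and give the texture
matrices spatially correlated noise to chew on, but they are
ellipsoids with stationary Gaussian texture: no anatomy, no partial
volume effects, no bias fields, no motion, no scanner noise floor.
Passing calibration and power checks therefore validates the
*machinery* — feature formulas, selection, the ranking protocol, the
null construction, the importance bookkeeping — not any claim about
real brains or the reproducibility of the study's specific areas,
whose raw data are unavailable.
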