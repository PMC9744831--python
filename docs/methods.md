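# Methods

This note documents the models and procedures `leukodrive` implements,
the conventions and numerical choices behind them, what the synthetic
data do and do not emulate, and the known limitations. It states no
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Lesion volumetry

The measurement model treats an observed FLAIR-like volume as

    v(x) = t(x) · b(x) + ε(x)

where `t` is a piecewise tissue intensity (lesions elevated above the
normal-white-matter level), `b` a smooth multiplicative inhomogeneity
field and `ε` i.i.d. Gaussian noise.

**Bias correction.** `b` is modelled as the exponential of a low-order
3-D polynomial (order 2 by default, coordinates normalized to [−1, 1])
and estimated by least squares on log-intensity over a mask of
nominally homogeneous tissue (cerebral WM + periventricular bands +
middle cerebellar peduncle). The fitted log-field is demeaned over the
mask so correction preserves the overall intensity scale; an option
keeps the constant term, in which case order 0 reduces to division by
the geometric mean. The full pipeline adds one robust refit that drops
voxels more than 4 robust SDs (1.4826·MAD) from the median residual, so
hyperintense lesion voxels inside the mask do not drag the polynomial
upward around them. A rank check on the design matrix rejects
degenerate mask geometries. Because the original study's correction is
available only as part of a larger software suite, this estimator is
the package's own, and it is validated against phantoms whose generating
field is known exactly.

**Reference-region standardization.** The middle cerebellar peduncle
(MCP) is taken as lesion-free white matter. Its mean μ and sample SD σ
(n−1 convention — the ROI is a sample used to estimate the population
SD; a trimmed variant is available) define the affine map

    v' = 1000 + 100 · (v − μ) / σ

after which the MCP has mean 1000 and SD 100 exactly. Standardization
is invariant to any positive affine rescaling of the input when the
reference statistics are re-estimated, which the tests assert. At
least 30 MCP voxels are required; σ = 0 is rejected.

**Segmentation and quantification.** A voxel is lesion iff
v' > 1000 + c·100 with cutoff c = 3.5 by default, restricted to the
search region (the four lobar WM labels plus the four periventricular
bands; MCP and other infratentorial tissue are excluded — leukoaraiosis
is by definition a cerebral white-matter lesion). The inequality is
strict; ties are measure-zero under continuous noise and excluded
explicitly for integer phantoms. No minimum component size is applied
by default (a 26-connectivity size filter is available). Volumes are
voxel count × dx·dy·slice-thickness in ml; the four periventricular
bands are pooled into one figure, and a voxel in a periventricular band
never also counts toward a lobe (the atlas stores one label per voxel,
and periventricular load dwarfs lobar load in the reference cohort, so
double counting would distort totals). Under Gaussian noise the
expected lesion-free false-positive fraction at c = 3.5 is the upper
tail P(Z > 3.5) ≈ 2.3×10⁻⁴, which the recovery tests check within
binomial error.

## Morphometry

Brain atrophy is BA = CFV/ICV = 1 − TBV/ICV with ICV = TBV + CFV; the
two published forms agree to 10⁻¹² and BA ∈ [0, 1) for valid inputs
(TBV > 0). Tissue classes come from a 3-class intensity segmentation:
either fixed thresholds or 1-D k-means over intracranial voxels with
clusters ranked by center. K-means clustering is rejected as
"fewer than three distinguishable modes" when the smallest center gap
does not exceed 3× the largest within-cluster SD — a unimodal
distribution split three ways produces gaps comparable to the
within-cluster spread, whereas separated tissue modes produce gaps many
times larger. Volumes are voxel counts × voxel volume (binary
densities); probabilistic tissue segmentation of real MRI is out of
scope.

## Behavioral scoring

**DMD ratio.** The published formula divides hits *plus false presses
on noise* by the total trial count. Counting false alarms in the
numerator of a recognition rate is surprising — it may be a misprint
for correct rejections — but the package does not guess intent: the
`verbatim` convention implements the formula literally and is the
default, a `corrected` convention (hits + correct rejections) is
exposed, and every scored output records which was used. The two
conventions differ by (n_noise − 2·false alarms)/n_trials, so they
coincide exactly when half the noise trials are pressed. Ratios are in
[0, 1] and multiplied by 100 when written into cohort tables, matching
the scale of the reference summary statistics.

**DSP scores.** Each of six course locations is rated 1–3 on a fixed
category set (P1: signalling/searching/steering; P2 and P6:
searching/speeding/signalling/positioning; P3 and P5:
searching/speeding; P4: searching/stability). Location scores are
category sums, the total is the sum over locations, and the legal
ranges (P1 3–9, P2/P6 4–12, P3/P4/P5 2–6, total 17–51) are enforced by
validation and property-tested over random assessments.

## Statistics

All estimators in the inference stage depend on the data only through
second moments, so they accept either a cohort table or a correlation
matrix + SDs directly — which is how the package reproduces the
reference study's numbers from its printed tables without raw data.

**Standardized regression.** β = R_xx⁻¹ r_xy, R² = r_xyᵀβ,
adj R² = 1 − (1−R²)(n−1)/(n−k−1), F = (R²/k)/((1−R²)/(n−k−1)) on
(k, n−k−1) df. A singular predictor block is reported together with the
offending eigenvector. The estimator is verified against least squares
on z-scored data constructed (by a Cholesky factor rotation) to carry
exactly the target sample correlation, to 10⁻⁸.

**Path analysis.** Recursive systems of regressions among observed
variables, with freely covarying exogenous variables and mutually
uncorrelated residuals — under these conventions the default model has
df = p(p+1)/2 − 12 = 3. The free parameters are the exogenous
covariance block, the path coefficients and the residual variances;
the implied covariance is Σ(θ) = (I−B)⁻¹Ψ(I−B)⁻ᵀ. The fit minimizes
the normal-theory discrepancy F_ML with an analytic gradient, starting
from the per-equation least-squares solution, which for this model
class (a Gaussian DAG model) is already the maximum-likelihood
estimate; BFGS polishes and the fit is accepted only if the gradient
sup-norm is below 10⁻⁸. Optimization runs on the correlation scale —
F_ML and all reported fit indices are invariant to per-variable
rescaling while the raw covariance here spans eight orders of magnitude
— and estimates are mapped back to original units afterwards.

**Fit indices.**

- χ² = (n−1)·F_ML by default. The Wishart (n−1) convention is chosen
  for consistency with the n−1 in the RMSEA denominator; χ² = n·F_ML is
  available because published software differs on this point.
- GFI = 1 − tr[(Σ⁻¹S − I)²]/tr[(Σ⁻¹S)²];
  AGFI = 1 − [p(p+1)/(2·df)](1−GFI), reported as absent when df = 0.
- RMSEA = √(max(χ²−df, 0)/(df·(n−1))); exactly 0 whenever χ² ≤ df.
- AIC = −2·logL + 2·(free parameters) with the multivariate-normal
  log-likelihood of S evaluated at Σ̂. The additive constant of AIC
  depends on conventions (divisor-n vs n−1 moments, constant terms)
  that differ across software, so AIC values are comparable within this
  package but not directly against other tools.

Correlation significance stars use the two-sided t test on n−2 df at
0.05/0.01/0.001. No multiple-testing correction is applied, matching
the reference analysis.

**Rounding propagation.** The packaged correlation matrix is printed to
two decimals, which makes the full 17-variable matrix slightly
indefinite (smallest eigenvalue ≈ −0.017, driven by the total-LA column
correlating 1.00 with periventricular LA) and perturbs every statistic
assembled from it. Cohort simulation therefore first projects the
matrix to the nearest positive-semidefinite correlation matrix
(eigenvalue clipping at 10⁻⁶ with diagonal rescaling, iterated; the
repair changes no entry by more than 0.02 and is recorded on the output).
The same rounding is why reproduced statistics are expected to match
published values only within rounding-propagation tolerance (e.g. χ²
to within a few tenths), not digit-for-digit.

## Synthetic data

The phantom atlas is a deterministic layered geometry in a fixed
template space: a CSF rim, a GM shell, lobar WM quadrants around a
central ventricle box with one-voxel periventricular bands, and an
infratentorial MCP block. Default geometry is 64×64×27 voxels at
0.9375 mm in-plane and 5 mm slices, matching the reference
acquisition's slice count and thickness; the in-plane FLAIR resolution
was not published, so the T1 matrix spacing is used and is
configurable. Generating phantoms directly in template space makes an
anatomical-normalization step unnecessary at this scale — an explicit
simplification.

FLAIR rendering assigns tissue means (CSF 150, WM/PV/MCP 500, GM 650,
arbitrary units), elevates lesion voxels by contrast × 50 (the nominal
normal-WM SD that defines contrast units), multiplies by the bias field
and adds Gaussian noise. The generator's bias field is itself
log-polynomial with max fractional deviation equal to the requested
amplitude, i.e. it lies in the estimator's model class; recovery
failures therefore indicate estimator defects, not model mismatch.
Lesions are rasterized spheres — ground-truth volume is the count of
voxel centers inside the radius times the voxel volume, not 4/3·πr³ —
and lesions overlapping the MCP are refused because they would corrupt
the reference distribution.

Cohort tables are multivariate normal with configurable moments
(defaults: the reference cohort's published means, SDs and repaired
correlation matrix, n = 101). DSP columns can be integerized by
rounding half-away-from-zero and clipping to their legal ranges, which
preserves means while respecting the 1–3 category scale; the rounded
total is clipped to 17–51 but not forced to equal the sum of the
rounded locations, since the reference table treats it as its own
variable.

What the synthetic data do *not* emulate: real brain anatomy and
registration error, Rician noise physics, T1/T2 multi-sequence
contrast, lesion shape irregularity, rater behavior in DSP scoring, and
non-Gaussian marginals of the cohort variables (LA volumes are strongly
right-skewed in reality). Passing recovery tests therefore demonstrates
correctness of the algorithms under their stated model, not performance
on clinical data.

## Problem sizes and determinism

The tests and the acceptance script run phantoms at 32×32×12 (recovery,
20 replicates) and 64×64×27 (false-positive rate), and cohort
simulations up to n = 10⁵ — sizes chosen so ground truth is well
resolved while each check completes in seconds. Sampling-error bounds
follow 3/√n (e.g. ±0.01 at n = 10⁵, ±0.3 at n = 101 for the maximum
over all 136 correlation pairs). All generators take explicit integer
seeds and are bit-reproducible for a fixed seed.

## Known limitations

- The threshold segmentation has no spatial regularization; at clinical
  noise levels partial-volume voxels at lesion rims are resolved only to
  within a one-voxel boundary shell, which is the guarantee the tests
  enforce.
- The published figure does not enumerate its path set; the default
  df = 3 model is the unique natural structure consistent with the
  published degrees of freedom, and `PathModelSpec` accepts any other
  recursive structure (adding parietal LA as a fourth exogenous
  predictor gives df = 4).
- Raw participant data are not public, so subject-level descriptive
  statistics cannot be reproduced; everything that depends on the data
  only through the printed summary tables can be, and is.
- Latent variables, correlated residuals, missing-data estimation and
  robust/bootstrap standard errors are out of scope.
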