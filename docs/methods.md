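# Methods

`lcgrad` estimates the internal functional organization of the locus
coeruleus (LC) — a small bilateral noradrenergic nucleus in the dorsal pons —
from resting-state BOLD data, summarizes it as a spatial gradient, and tests
how that gradient relates to age, behavior, and clinical screening status.
This note documents the model, its assumptions, the tunable parameters, the
synthetic phantom used for validation, and the numerical and design choices
where more than one defensible option existed.

## Gradient estimation (connectopic mapping)

For each subject, every ROI voxel's time series is correlated with the mean
series of every target parcel, giving a *connectivity fingerprint* per voxel
(a vector of Pearson correlations). Similarity between two fingerprints a, b
is the eta-squared measure

    eta^2 = 1 - sum_i[(a_i - m_i)^2 + (b_i - m_i)^2]
              / sum_i[(a_i - M)^2 + (b_i - M)^2],

with m_i = (a_i + b_i)/2 and M the grand mean of both vectors; it lies in
[0, 1] and equals 1 for identical profiles. The voxel-by-voxel similarity
matrix is turned into a weighted graph by keeping edges above the *largest*
threshold that still leaves the graph connected (binary search over the
sorted unique off-diagonal similarities). This rule is our choice: "connected
graph" admits many constructions, and the maximal connectivity-preserving
threshold is deterministic, auditable (the threshold is logged in every
result), and sparsifies as much as the topology allows.

The gradient is the generalized eigenvector of the graph Laplacian,
(D − W) v = λ D v, with the smallest nonzero eigenvalue — the direction of
maximal stepwise change in connectivity. Since ROI graphs here have at most
a few hundred nodes we solve the dense symmetric problem exactly
(`scipy.linalg.eigh` with the degree matrix on the right-hand side); tests
verify agreement with an independent route through the symmetric normalized
Laplacian. The eigenvector sign is arbitrary, so the gradient is flipped, if
needed, to correlate positively with the anterior–posterior world coordinate
(rostral = high), then min–max scaled to [0, 1].

Two conventions deserve emphasis:

* **Hemispheres.** Fingerprints and similarity are computed jointly, but the
  graph and eigenmap are built per hemisphere, because left and right
  trend-surface parameters are analyzed separately downstream. Whether one
  bilateral eigenmap would behave differently is untested here.
* **Group gradients** average the *similarity matrices* of the member
  subjects and decompose once, rather than averaging per-subject
  eigenvectors. Individual eigenvectors have arbitrary sign and unstable
  ordering; averaging upstream of the decomposition avoids any alignment
  step.

Scaled gradient values are rounded to 9 decimals. This is far below any
meaningful signal resolution, and it makes voxels that are exactly
symmetric in a noiseless phantom exactly tied, so rank-based comparisons
against planted fields behave as the geometry dictates rather than as
floating-point tie-breaking happens to fall.

Voxels with zero temporal variance are excluded from the correlation stage;
their gradient value is imputed afterwards as the mean over in-mask
6-neighbours (logged).

## Trend-surface model (TSM)

A gradient's spatial layout is summarized per hemisphere by regressing its
values on nine pure-power coordinate terms — x, y, z, x², y², z², x³, y³, z³
— with no cross-terms. Coordinates are world mm, z-scored per hemisphere so
that coefficients are comparable across hemispheres and across phantoms of
different physical size (the normalization is a package choice; nothing
enforces one). The left hemisphere's x-axis is sign-flipped before z-scoring
so "lateral" is positive on both sides; a mirror-symmetric field therefore
yields identical left and right coefficients, which is what makes the
left-minus-right asymmetry profile (|β_L − β_R| per term, plus its Euclidean
norm) interpretable.

The fit is Bayesian linear regression with an isotropic Gaussian prior on
the nine slopes and an unpenalized intercept. The prior precision α and
noise precision τ are set by evidence maximization (MacKay fixed-point
updates on the effective degrees of freedom γ: α ← γ/‖m‖², τ ← (n−γ)/RSS),
iterated until the relative change in α falls below 1e-6 or 200 iterations.
One eigendecomposition of XᵀX serves all iterations. When the data dominate,
α/τ → 0 and the posterior mean converges to least squares; a constant field
drives α to its cap and all slopes to zero. Precisions are clipped to
[1e-10, 1e12] to keep degenerate inputs (perfect fits, constant fields)
finite. Tests cross-check the posterior mean against scikit-learn's
`BayesianRidge` with flat hyperpriors. Downstream analyses consume only the
9 slopes per hemisphere (18 bilaterally); the intercept is reported but not
analyzed.

## Cohort statistics

Individual gradient estimates in a nucleus this small are noisy, so all
inferential analyses work on *group* gradients:

* **Age:** an average gradient per integer year of age; a nested F-test asks
  whether the 18 TSM parameters explain the bin year beyond bin-mean sex,
  and each parameter is rank-correlated with year (partial Spearman
  controlling sex, BH-FDR over the 18-parameter family).
* **Behavior:** subjects sorted by a cognitive score; windows of 20 subjects
  slid in steps of 5; per window a group gradient, its 18 TSM parameters,
  and window means of the score and of the nuisance covariates (age, sex,
  education). Windows form the rows of the same nested F-test plus
  per-parameter partial Spearman correlations.
* **Clusterability:** per-subject Calinski–Harabasz index of a k=2 k-means
  split of the subject's own gradient values, rank-correlated with age
  controlling sex. The 1-D k-means is seeded at the 25th/75th percentile
  quantiles, which deterministically finds the contiguous optimum.
* **Group contrast:** subjects screened by HADS (anxiety *or* depression
  subscore above 7, here a single generated score above 7); because such
  groups are imbalanced, each bootstrap iteration draws 20 subjects per
  group with replacement, computes the group gradient and its 18 TSM
  parameters, and the two collections of parameter vectors are compared by
  one-way MANOVA (Pillai's trace with the standard F approximation) plus
  per-parameter Mann–Whitney U tests under BH-FDR.

Implementation notes. The nested F-test uses the textbook decomposition
F = [(RSS₀−RSS₁)/(p₁−p₀)] / [RSS₁/(n−p₁−1)] with partial R² =
(RSS₀−RSS₁)/RSS₀ and an Ezekiel-style small-sample adjustment
1 − (1−R²)(n−p₀−1)/(n−p₁−1); numerical identity with any particular
statistics package's "adjusted partial R²" is not claimed. Partial Spearman
rank-transforms the two variables *and* the covariates before linear
residualization (the standard convention; it also makes "y equals a
covariate" yield exactly zero partial correlation, returned as ρ=0, p=1
rather than an error). Mann–Whitney uses exact enumeration over all
assignments (tie-aware) when both samples have ≤ 8 observations and the
normal approximation with tie and continuity corrections otherwise. BH-FDR
is the step-up rule with monotonicity enforcement; note that the adjustment
is *not* idempotent (re-adjusting adjusted values inflates them), so no such
property is relied on. The FDR family is the 18 TSM parameters within one
analysis, one family per score.

### Calibration — what holds and what provably does not

Every inferential primitive (nested F, partial Spearman, Mann–Whitney,
MANOVA, bootstrap MANOVA on exchangeable replicates) is verified to reject
at the nominal 5% under its null simulation; the acceptance battery
recomputes these rates (400 replicates each; 100 meta-replicates of 100
bootstrap iterations).

Two *procedure-level* caveats are empirical findings of this package and
should temper interpretation of windowed and bootstrap results anywhere the
design is used:

1. **The sliding-window F-test does not control type-I error.** Subjects are
   sorted by the outcome score, windows overlap (adjacent windows share 15
   of 20 members), and the F-test treats windows as independent rows. Under
   a score that is pure noise, the windowed F-test rejects at roughly 60%,
   not 5% (spurious regression between smooth moving averages). The windowed
   analysis is therefore a descriptive effect-size device — its partial R²
   summarizes association strength at the window level — not a calibrated
   test. Our power criterion asks only that planted couplings are detected.
2. **Bootstrap-replicate MANOVA is anticonservative across disjoint
   pools.** Replicates resampled from the same pool are not independent
   subjects; with two disjoint pools drawn from one population the
   replicate-level MANOVA rejects essentially always. Calibration holds in
   the exchangeable case (both groups resampled from an identical pool),
   which is what the null study uses. Group-contrast p-values from this
   design should be read as ranking evidence, not as frequentist error
   rates.

## The synthetic phantom

The phantom generates everything the pipeline consumes, with known ground
truth. Geometry: two mirror-symmetric columns of 2×12×2 voxels (48 per
hemisphere, 2 mm isotropic by default) elongated along the
anterior–posterior axis, with a gentle per-slice lateral/dorsoventral
stagger. The stagger matters: a perfectly rectangular column has only two
distinct coordinate values on the short axes, making x² constant and x³
collinear with x, i.e. a degenerate cubic basis; the curved column gives
every axis at least four distinct values (and is closer to the real nucleus,
which is a curved cell column). Parcels are contiguous 2×2×2 blocks placed
on a lattice away from the ROI, a third tagged as rostral-like targets and a
third as caudal-like targets.

Signal model per subject: two latent unit-variance white signals s_rostral
and s_caudal with correlation 0.3 (distinct but not orthogonal — perfect
separability would make the problem trivially easy). Each ROI voxel mixes
them as g·s_rostral + (1−g)·s_caudal, normalized to unit variance, plus
white noise of SD `noise_sd`. The planted field g is logistic in the
normalized long-axis coordinate: midpoint at 1 − `rostral_extent` (the
fraction of the nucleus on the rostral-like side) and slope `steepness`
(sharper transition → more clusterable gradient). Target parcels carry the
matching latent; neutral parcels carry their own independent latent.

Cohort defaults (the study conditions; chosen once, a priori, as plausible
for the phenomenon being emulated):

| parameter | default | meaning |
|---|---|---|
| `base_rostral` | 0.6 | rostral-like fraction at the mean age |
| `age_slope` | −0.005 /yr | loss of rostral-like extent with age |
| `base_steepness`, `steepness_slope` | 6.0, +0.06 /yr | sharper (more clustered) transition with age |
| `rostral_noise_sd`, `steepness_noise_sd` | 0.05, 0.5 | between-subject spread |
| `em_effect`, `er_effect` | 1.5 | score coupling per SD of the planted quantity, against unit score noise |
| `hads_shift` | −0.12 | additional rostral-like loss in screen-positive subjects |
| `noise_sd` | 0.1 | voxel noise relative to unit-variance signal |
| `n_timepoints` | 200 (150 in validation studies) | series length |

`base_rostral` is 0.6 rather than 0.5 deliberately: the linear-y TSM
coefficient is symmetric in the logistic midpoint about 0.5, so a cohort
centred at 0.5 would have a non-monotone age→β_y coupling by construction;
0.6 keeps the planted decline monotone and matches the rostral-dominant
phenotype in the young. The emotional-memory-like score couples to the
planted linear-y coefficient (standardized within cohort), the
reactivity-like score to `rostral_extent`; all other scores are pure noise,
so analyses can be checked against both true couplings and nulls. Ages are
uniform on 18–88; sex is Bernoulli(½); education is a truncated normal
matching a typical cohort summary (mean 14.6 y, SD 4); the HADS-like score
is a rounded folded normal putting ≈20% of subjects above the screening
threshold.

What the phantom does **not** emulate: temporal autocorrelation and
physiological noise spectra, motion, scanner drift, spatial noise
correlations, registration error, or any cortical geometry — parcels are
abstract signal sources. Passing recovery tests therefore shows the
pipeline's correctness and its noise robustness under white noise, not
performance on real fMRI.

## Problem sizes and determinism

Validation studies use sizes chosen to make their Monte Carlo error small
relative to the margins being tested: 10⁴ fingerprint pairs for the
similarity oracle; 200 random graphs (≤12 nodes) for the eigenmap oracle;
20 seeds × 3 noise levels for gradient recovery; 100 coefficient draws for
TSM recovery; 400 replicates for each null rate (100 meta-replicates × 100
iterations for the bootstrap); 50 seeds of n=292 cohorts — a realistic
lifespan-subsample size for this windowed design, giving 55 windows — for
the power battery, with 100 bootstrap iterations per cohort (the API
default is 1000).

Everything is deterministic given a seed: phantom generation, graph
thresholding, eigendecomposition, k-means seeding, and bootstrap draws. The
only warning-level nondeterminism is the eigenmap's repeated-eigenvalue
check, which flags (but does not resolve) gradients whose direction is
numerically unstable.

## Known limitations

* The evidence-maximization updates are not guaranteed monotone in the
  marginal likelihood; in practice the trajectory is monotone to 1e-6,
  which a test asserts.
* The maximal-threshold graph rule can produce very dense graphs when
  similarities are uniformly high (small, smooth ROIs); that is the
  intended behaviour but makes the eigenmap less local.
* Whether the original analyses used 9 or 18 TSM regressors in the nested
  F-model is unknown; 18 (bilateral) is the default here.
* The asymmetry index (Euclidean norm of |β_L − β_R|) is one of several
  reasonable scalarizations; no claim is made that it matches any other
  software's operationalization.
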