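# Methods

This note documents the statistical model behind `asymmorph`, the numerical
conventions it fixes, what the synthetic-data generators do and do not
emulate, and the design choices that were genuinely open.

## Procrustes superimposition

Configurations are centred, rescaled to unit centroid size, and rotated to
a least-squares fit. Rotations are solved by cross-covariance SVD with a
determinant correction, so improper rotations (reflections) are excluded
unless explicitly requested — bilateral structures must not be silently
mirrored onto each other.

Generalized Procrustes analysis iterates: rotate all observations onto the
running consensus, recompute the consensus (re-centred, re-scaled to unit
centroid size), repeat until the consensus root-mean-square change falls
below `tol = 1e-10` (maximum 100 iterations; non-convergence raises an
error carrying the last residual). Shape variation in the intended
applications is small, and the fit typically converges in fewer than 10
iterations. Scaling is full-Procrustes (every observation at unit centroid
size) throughout; there is no partial-Procrustes option.

**Orientation.** The converged solution of a plain GPA is rotated into the
consensus principal-axis frame, with axis signs fixed by the
largest-magnitude coordinate per axis (determinant-corrected). This makes
the output a function of the shapes alone — re-running with arbitrarily
rotated, translated or rescaled copies of the inputs reproduces the same
aligned coordinates to 1e-8. In the object-symmetry fit the consensus is
instead kept in the mirror-locked frame (plane orthogonal to axis 0), since
a principal-axis rotation could move the mirror plane; all downstream sums
of squares are rotation-invariant, so this choice affects only the
coordinate frame of exported components.

**Tangent projection.** Analyses operate directly on Procrustes residual
coordinates without an additional orthogonal tangent-space projection. At
the variation scale the pipeline targets (Procrustes SS of order 1e-3 on
unit-size shapes) the projection changes nothing at the reported precision;
the curvature of shape space only becomes visible as the second-order
effects discussed under *Linear-regime caveats* below.

## Object symmetry

A structure with object symmetry is analysed by jointly superimposing the
2N set of originals and reflected-relabeled copies. The mirror plane is the
coordinate plane orthogonal to the first axis; since the joint fit
re-rotates everything, the choice is immaterial and fixing it makes output
deterministic. The consensus is symmetrised at every GPA iteration (average
of itself and its reflected-relabeled copy), so it is exactly symmetric and
the symmetric/asymmetric split is exact:

* symmetric component = (aligned original + aligned mirror) / 2
* asymmetric component = (aligned original − aligned mirror) / 2

The split conserves energy (`sum ||aligned||^2 = sum ||sym||^2 + sum
||asym||^2`) and the components transform correctly under reflection
(symmetric invariant, asymmetric negating).

**Subspace dimensions.** For k landmark pairs and u median (midline)
landmarks, after removing location, scale and orientation:

| D | symmetric s   | asymmetric a  |
|---|---------------|---------------|
| 2 | 2k + u − 2    | 2k + u − 2    |
| 3 | 3k + 2u − 4   | 3k + u − 3    |

These are the standard object-symmetry dimension formulas and are used for
all degrees of freedom. Published tables in this literature sometimes imply
different per-trait dimensions, because analyses are often run on
undisclosed landmark subsets; the package always derives s and a from the
declared symmetry map and does not attempt to force agreement with any
particular printed table.

## Procrustes ANOVA

The two-factor mixed design crosses individuals (random) with sides
(fixed; original vs. mirrored copy), replicates at the bottom. Writing
`sym_i`, `asym_i` for specimen means over replicates and `sym`, `asym` for
grand means, the Procrustes sums of squares over the 2N augmented set are

    SS_Individual = 2r * sum_i ||sym_i − sym||^2          df = (n−1) s
    SS_Side       = 2nr * ||asym||^2                      df = a
    SS_Ind×Side   = 2r * sum_i ||asym_i − asym||^2        df = (n−1) a
    SS_Error      = 2 * sum_ij (||sym_ij − sym_i||^2
                              + ||asym_ij − asym_i||^2)   df = n(r−1)(s+a)

identical to an explicit two-factor ANOVA looped over specimens, sides,
replicates and coordinates (verified against such a loop in the tests).
F ratios follow the mixed model: Individual and Side over the interaction,
the interaction over measurement error; P values are parametric (F
distribution), matching the usual presentation of such tables. Permutation
P values are a possible extension, not implemented.

Only balanced designs (equal replicates per specimen) are accepted;
unbalanced data must be pre-averaged or subsetted by the caller, since
unbalanced mixed-model Procrustes ANOVA needs machinery out of scope here.
With r = 1 the error stratum is absent and the interaction has no test.

**Expected mean squares and variance components.** Because every
observation enters twice (original + mirror), each mean square carries a
factor 2 relative to the per-coordinate effect variances of the generating
model:

    E[MS_Error]    = 2 σ²_me
    E[MS_Ind×Side] = 2 (r σ²_fa + σ²_me)
    E[MS_Individual] = 2 (r σ²_ind + σ²_me)

`variance_components` inverts these by method of moments. Isotropic
per-coordinate noise projects onto the (s+a)-dimensional tangent space as
white noise with the same per-dimension variance, which is why the raw
generator sigmas are recovered directly; the parameter-recovery suite
confirms agreement within a few percent at n = 200.

**Individual FA scores.** The scalar FA score of a specimen is the
Procrustes (Euclidean) norm of its replicate-averaged asymmetric component
after subtracting the sample mean asymmetry (DA correction, on by
default). The Euclidean norm is preferred over a Mahalanobis distance
because cross-population Levene comparisons need a scalar magnitude that
remains stable at the modest sample sizes typical of this work, without
inverting a high-dimensional covariance.

## Levene's test

Cross-population FA comparisons (shape scores and unsigned count
differences) use Levene's statistic on absolute deviations from the group
centre. The centre is the group **median** (Brown–Forsythe variant) by
default, consistent with the robustness rationale for using Levene's test
on FA data in the first place; mean-centring is available by flag. The
degenerate all-constant case returns (W, P) = (0, 1). Type-I error is
calibrated by simulation in the acceptance suite (rejection rate within
[0.03, 0.07] at alpha = 0.05); on integer counts the test runs slightly
conservative because rounding discretises the deviations.

## Meristic FA pipeline

Fixed step order on signed differences d = R − L:

1. **Grubbs screen** — iterated two-sided Grubbs test at alpha = 0.05, one
   removal per iteration until no rejection; zero-variance samples are kept
   untouched. Two-sided masking (simultaneous extreme outliers on both
   sides) is a known limitation of the iterated one-at-a-time procedure.
2. **Size dependence** — Spearman rho of |d| against trait size (R+L)/2;
   size-dependent FA would confound between-sample comparisons.
3. **Normality** — Shapiro–Wilk on d; ideal FA is normal with mean zero,
   and bimodality indicates antisymmetry, which disqualifies the trait as
   an instability proxy.
4. **DA** — one-sample t of d against zero.
5. **Indices** — FA1 = mean|d|; FA4a = 0.798·sqrt(var(d)) with the n−1
   denominator. 0.798 is the conventional rounding of sqrt(2/π) (E|X| =
   sqrt(2/π)·σ for centred normal X), so FA1 and FA4a estimate the same
   quantity under ideal FA while FA4a ignores any DA shift. The report
   also flags whether |mean(d)| exceeds FA4a — if not, between-sides
   variation is attributed mainly to developmental instability.

Counts are treated as error-free integers (no measurement-error stratum).
No multiple-testing correction is applied across traits or populations;
all raw P values are reported so users can adjust as they see fit.

**Allometry ANCOVA.** Per-population least squares of (R+L)/2 on body
size; slope homogeneity is the size×population interaction term of the
joint linear model (type-II ANOVA). The default is untransformed axes,
with a log10–log10 option for power-law allometry; which scale is
appropriate is data-dependent and deliberately left to the caller. An
exact (zero-residual) fit makes the F test 0/0, in which case the
interaction P is decided directly from the fitted slopes (1 if equal, 0
otherwise).

## Synthetic data

`simulate_landmarks` draws

    observation(i, rep) = template + sym_i + da + fa_i + noise_irep

with `sym_i` the symmetric projection of isotropic N(0, σ²_ind) noise,
`fa_i` the antisymmetric projection of N(0, σ²_fa) noise, `da` a fixed
antisymmetric field orthogonalised against the similarity-transform tangent
directions (so superimposition cannot absorb any of it and the mean
asymmetric component recovers it one-to-one), and raw N(0, σ²_me)
digitising noise. Defaults — n = 33 individuals, r = 2 replicates,
(σ_ind, σ_fa, σ_me) = (0.03, 0.01, 0.003) in shape units on the
unit-centroid-size template, ‖da‖ = 0.02 — put symmetric individual
variation an order of magnitude above FA and FA a few times above
digitising noise, with all ANOVA strata clearly detectable at these sample
sizes: the regime of a well-executed replicated digitising study on a
modest fossil sample. The built-in template is a stylised 2D oral view of
a spatangoid echinoid test (21 landmarks: 9 pairs + 3 medians) stored with
the mirror plane at axis 0 = 0 so its symmetry is exact in floating point.

`simulate_meristic` draws sizes uniform on 30–60 (test length, mm), mean
count 5 + 0.9·size (pore pairs per petal rising ~0.9 per mm), splits sides
as R, L = μ ± (da_shift + e_i)/2 with e_i ~ N(0, σ²_fa_count), and rounds
to integers by default. Defaults da_shift = 0.57, σ_fa_count = 1.45 give
FA4a ≈ 1.16 — the scale of a weakly asymmetric petal count in a
moderate-instability population. Rounding is applied after side-splitting,
which attenuates FA realistically for σ ≲ 1 and biases FA4a slightly
downward there; the continuous option (`rounding=False`) exists exactly so
that distributional identities (e.g. FA1/FA4a → 1) can be checked without
that attenuation.

**What the generators do not emulate.** Landmark noise is isotropic and
uncorrelated across landmarks, individuals are exchangeable (no allometric
or spatial structure in shape), DA is a single fixed field, and there is no
antisymmetry (bimodal d) option. Passing tests therefore demonstrate
correctness of the estimators under the stated variance-component model,
not robustness to correlated digitising error, landmark-specific noise, or
mixture-type asymmetries in real material.

**Linear-regime caveats.** Unit-size scaling makes shape space a sphere;
generated symmetric/asymmetric perturbations are exactly (anti)symmetric
before superimposition, but alignment leaks second-order terms
(O(amplitude²)) across components. Invariants stated "to 1e-8" — e.g.
purely antisymmetric samples having constant symmetric components, or
component covariance ranks matching the s/a formulas at strict thresholds —
are therefore verified at small amplitude (σ ~ 1e-5); at the default
amplitudes the leakage is of order 1e-4 and harmless to the ANOVA, whose
estimates recover the generating components within a few percent.

## Numerical conventions

- Landmark indices are 0-based internally; file formats (symmetry-map JSON,
  figure-style numbering) are 1-based and converted only at the I/O
  boundary.
- Missing or non-finite coordinates are hard errors everywhere; there is no
  imputation, matching the practice of excluding inadequately preserved
  specimens rather than repairing them.
- PCA is covariance PCA (never correlation) on flattened coordinates;
  loading signs are fixed by making each component's largest-magnitude
  loading positive; retained rank is min(N−1, p) with zero eigenvalues
  kept so variance fractions always sum to 1.
- The sample-wide PCA is run on replicate-averaged specimens; component
  PCAs within the symmetry decomposition are run at observation level.
- GPA convergence tolerance 1e-10 (consensus RMS change), max 100
  iterations; zero centroid size and rank-zero cross-covariances raise
  degenerate-configuration errors.
- All simulation randomness flows through a single integer seed per
  generator call (`numpy.random.default_rng`); identical parameters and
  seed give byte-identical serialised output.

## Known limitations

- Balanced designs only in the Procrustes ANOVA; no permutation tests; no
  Mahalanobis FA scores; no sliding semilandmarks or missing-landmark
  estimation.
- Matching symmetry (two separate mirrored structures) is out of scope;
  only object symmetry is supported.
- 3D object symmetry is implemented (dimension formulas, reflection), but
  the shipped template and the bulk of the validation suite are 2D.
- The Grubbs screen can mask paired opposite-side outliers (above).
- Categorical traits are tabulated, not tested; count FA indices beyond
  FA1/FA4a (repeatability-corrected variants) are not provided because the
  meristic design assumes error-free counts.
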