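# Methods

## Model and estimation

### Genotypes and the GRM

Genotypes enter as reference-allele counts `r_ij ∈ {0,1,2}`. With allele
frequency `f_j` (by default estimated in-sample as half the column mean;
externally supplied frequencies are accepted), the standardized genotype is
`z_ij = (r_ij − 2f_j)/√(2f_j(1−f_j))`. Missing genotypes are mean-imputed
to `2f_j` *before* standardization, so they contribute exactly zero to the
standardized column and column means stay at zero; this is standard GRM
practice. Monomorphic markers (f ∈ {0,1}) cannot be standardized: the
matrix-level API drops them with a warning, the scalar operation errors.

The GRM is `G = ZZᵀ/m`. Relatedness pruning removes subjects until every
off-diagonal entry is at or below a threshold (0.025 ≈ second cousins is
the conventional cut): the rule is greedy — repeatedly drop the subject in
the most over-threshold pairs, ties broken by larger mean relatedness and
then lexicographic id. Greedy removal keeps close to the maximum number of
subjects without solving the (NP-hard) maximum independent set exactly.
GRM principal components, usable as ancestry covariates, are the top
eigenvectors with the sign convention that each component's
largest-magnitude loading is positive.

### REML variance components

For a trait y with covariates C and covariance `Ω = Gσg² + Iσe²`, the
restricted log-likelihood (constants dropped) is

```
l2 = −½ ( ln|Ω| + ln|CᵀΩ⁻¹C| + yᵀPy ),
P  = Ω⁻¹ − Ω⁻¹C(CᵀΩ⁻¹C)⁻¹CᵀΩ⁻¹ .
```

Fitting reparameterizes by (h², σp²) with `Ω = σp²(h²G + (1−h²)I)`,
eigendecomposes G once (`G = UDUᵀ`), and works in the rotated basis where Ω
is diagonal: each likelihood evaluation costs O(np²) instead of O(n³).
σp² profiles out in closed form (`σp² = yᵀP₁y/(n−p)` at unit scale), and
the one-dimensional profile over h² ∈ [0, 1−10⁻⁶] is maximized by a
51-point grid scan followed by bounded scalar refinement (xatol 10⁻⁸). The
grid scan guards against the rare non-unimodal profile; the eigendecomposition
can be reused across traits sharing one GRM. Estimates within 10⁻⁵ of a
boundary are reported as exactly 0 or 1 with a `boundary` flag rather than
as errors. β is the GLS estimate `(CᵀΩ⁻¹C)⁻¹CᵀΩ⁻¹y` at the fitted Ω. An
optional standard error for h² comes from the curvature of the profile
likelihood by central finite differences (step 10⁻³); it matches the
Fisher-information bound on simulated data. If G is numerically the
identity (‖G−I‖_F/√n < 10⁻⁶) the fit refuses: σg² and σe² are confounded.

### The inverse problem

Pinning the variance components at their ideal values (σg² = 1, σe² = 0)
turns Ω into G and the restricted likelihood of a candidate trait y = Xw
into a quadratic form. With

```
P = G⁻¹ − G⁻¹C(CᵀG⁻¹C)⁻¹CᵀG⁻¹        (objective; PC = 0)
J = I − C(CᵀG⁻¹C)⁻¹CᵀG⁻¹,  Q = JᵀJ/n  (constraint; QC = 0)
```

the program is: minimize `(1/n)wᵀXᵀPXw + (λ/d)‖w‖₁` subject to
`wᵀXᵀQXw = 1`. The constraint equals the covariate-corrected sample
variance of the trait, so feasible traits are on a common scale. Both
quadratic forms are symmetrized `(M+Mᵀ)/2` against round-off; an intercept
column is always ensured in C. Before inversion G receives a relative
ridge `τ = 10⁻⁸·tr(G)/n`, escalating tenfold to at most `10⁻⁴·tr(G)/n` if
the Cholesky factorization fails — GRMs from finite marker panels are
routinely near-singular — and all inversions go through factorizations.
No small-sample correction is applied inside P or Q.

### The SQP solver

Splitting `w = u − v` with `γ = [u; v] ≥ 0` makes the L1 norm the linear
term `(λ/d)Σγ`; at any optimum min(uᵢ, vᵢ) = 0, so Σγ = ‖w‖₁. The split
program (quadratic objective, one quadratic equality g₁, sign constraints)
is solved by SQP from the fixed start u = 1, v = 0, α = 1:

1. Build the Lagrangian Hessian `∇²L = 2Hᵀ(P/n + α₁Q)H` in γ-space. If its
   smallest eigenvalue is negative (possible when α₁ < 0) shift by
   `(|λ_min| + 10⁻⁸)·I` — the convexification guarantees a solvable QP and
   a descent direction.
2. Solve the QP subproblem (linearized equality, bound constraints) with
   SLSQP from a near-feasible start. Subproblem iterates are accepted on
   explicit feasibility (equality residual ≤ 10⁻⁸ relative), not on the
   subsolver's exit flag: on degenerate QPs — the split Hessian is always
   rank-deficient along (δ, δ) directions — the subsolver can hit its
   iteration cap while already holding an excellent point. If the
   linearized constraint is incompatible with the bounds, an elastic
   relaxation with penalized slack on the equality row restores progress.
   Equality and bound multipliers are recovered from the QP stationarity
   condition restricted to the free set.
3. Backtracking Armijo line search (factor ½, slope 10⁻⁴, floor 10⁻¹⁰) on
   the exact-penalty merit `f + μ|g₁|`, with `μ ← max(μ, |q₁| + 10⁻²)`.
   Steps must strictly decrease the merit; on line-search failure the
   Hessian shift is escalated tenfold and the step recomputed.
4. Update `γ ← γ + s·p̂`, `α ← α + s·(q̂ − α)` until the KKT residual
   (stationarity and complementarity, relative to 1 + ‖∇f‖∞) is ≤ 10⁻⁶
   with |g₁| ≤ 10⁻⁸, or 500 iterations.

After convergence the common mass min(uᵢ, vᵢ) is subtracted from both
halves (all quadratic forms depend on γ only through w, and the linear term
cannot increase, so this preserves the KKT point while enforcing exact
complementarity), the sign is canonicalized so the largest-|wᵢ| entry is
positive, and coefficients below 10⁻⁸ are reported as exact zeros. The
program is non-convex (quadratic equality), so only local convergence is
guaranteed; an optional seeded multi-start perturbs the initial point and
keeps the best KKT point. In testing, single-start solutions match the
generalized-eigendecomposition global optimum at λ = 0 on 100/100 random
instances (d ≤ 6).

### Penalty tuning and evaluation

λ is tuned by repeated k-fold CV (default 10 × 3-fold over a grid of 21
values, 0 to 0.04 in steps of 0.002): per fold, the component is fit on the
training subjects (P and Q rebuilt from the training block of the GRM),
the held-out subjects are scored, and their trait h² is estimated by REML
on the held-out GRM block. Held-out estimates never touch training
subjects (disjointness is asserted). The chosen λ maximizes mean held-out
h², ties to the smallest λ (parsimony). The GRM is computed once on all
subjects and sub-setted per fold; allele frequencies are not re-estimated
per fold, matching standard chip-h² practice. Covariate columns are fixed
across folds; β is re-estimated inside every REML fit. A fold whose REML
fails is recorded as missing with a warning and excluded from the mean.

A fitted trait is evaluated by "evaluation CV": its h² re-estimated on
repeated random 2/3 subject subsamples (default 10), reporting mean and sd.
Comparators: the equal-weight trait (row sums — the symptom count), and
recovery errors `SE(w) = ‖w − ŵ‖²`, `SE(y) = (1/n)Σ(yᵢ − xᵢᵀŵ)²` after
sign alignment (the objective is sign-invariant).

## Synthetic data

The generator reproduces the structure of the validation study:

* **Genotypes**: m independent biallelic loci, frequencies
  `f_j ~ U(0.05, 0.5)`, counts `Binomial(2, f_j)`. Real genotypes have LD;
  independence changes nothing in the variance-component logic the tests
  exercise, but it does *lower* the statistical information of the GRM —
  with n = 1752, m = 2000 the per-trait GREML standard error is ≈ 0.039,
  about twice what LD-structured panels of the same size give. Tests that
  compare average estimates to targets inherit this Monte-Carlo width.
* **Heritable features**: `x = Zu + ε` with `u_j ~ N(0,1)` and
  `var(ε) = var(Zu)(1/h² − 1)`, pinning the realized genetic:residual
  variance ratio at the target. By default the genetic values are rescaled
  to sample variance h² so features have total variance ≈ 1: heritability
  is invariant to the overall scale, and unit scale makes covariate
  effects of a few tenths meaningful (raw Zu has variance ≈ m). The raw
  scale remains available (`unit_variance=False`).
* **Setting 1**: four features at h² = 0.2, a composite y₁ at h² = 0.8
  drawn independently by the same procedure, and a fifth feature solved
  from the implanted weights w = [0.22, 0.67, 0.60, 0.30, 0.22] so that
  `X[:, :5]·w = y₁` holds bit-exactly; irrelevant features are N(0,1)
  noise. y₁'s marker effects are drawn independently of the four features'.
* **Setting 2**: the five relevant features additionally carry fixed
  covariate effects `Cβ` with β = (0.2, 0.5) for sex ~ Bernoulli(½) and
  standardized age ~ N(40, 10²); the composite inherits `(Σwᵢ)·Cβ` through
  the weight identity. Irrelevant features are covariate-only (Cβ + noise).
* Discovery and validation cohorts come from disjoint sub-seeds of one
  seed; everything is reproducible bit-for-bit from that seed.
* The GRM handed to analyses is built from the causal markers themselves,
  as is standard when the causal variants of a simulated trait are known.

What passing simulation tests do **not** show: behavior under LD,
ascertainment, case-control sampling, realistic allele-frequency spectra,
missing clinical data, or population stratification beyond what GRM
principal components capture.

## Problem sizes in the test suite

Full-scale checks (1,752 × 2,000, the study condition) run in the
acceptance suite: REML calibration of the designed features averaged over
the discovery and validation suites, component recovery at λ = 0
(validation h² ≈ 0.8), covariate-effect recovery over 10 replicate cohorts,
and null-feature calibration. Distributional properties that need many
replicates (parameter recovery across h² targets, the overfitting
direction with ≥ 25 irrelevant features) run at reduced cohort sizes
(n = 350–500, m = 450–600) with correspondingly wider Monte-Carlo bands —
the estimator is scale-free in n, so these sizes probe the same code paths
at equivalent statistical difficulty per subject.

## Known limitations

* One variance component / one GRM; no bivariate REML, no region-restricted
  or multi-kernel GRMs.
* L1 penalty only (no L2 or group-lasso variants), linear combinations only
  (no kernelized traits).
* The equality-constrained program is non-convex; the solver certifies KKT
  points, not global optima. Multi-start mitigates but does not remove this.
* Greedy relatedness pruning is a heuristic; it matches exhaustive search on
  small instances but carries no optimality guarantee.
* The file surface reads variant-major PLINK .bed and the GCTA binary GRM
  dialect; VCF is out of scope (convert upstream).
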