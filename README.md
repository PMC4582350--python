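# heritcomp

Sparse heritable-component analysis: find the linear combination of clinical
variables whose composite trait has the highest **chip heritability** — the
fraction of phenotypic variance explained by genotyped SNPs in apparently
unrelated individuals.

## Who this is for

Complex diseases are assessed through many clinical variables (symptoms,
ages of onset, counts), each only partly genetic. Association studies and
genomic prediction both work better on more heritable traits, so it pays to
*refine* a multivariate phenotype into a single highly heritable quantitative
trait before genetic analysis. `heritcomp` does this directly against
genome-wide SNP data: no pedigrees, no single-causal-variant assumption.

## The model

Chip heritability of a trait **y** rests on the mixed model

```
y = Cβ + Zu + ε,     Cov(y) = Ω = G σg² + I σe²,     G = ZZᵀ/m
```

with standardized genotypes `z_ij = (r_ij − 2f_j)/√(2f_j(1−f_j))`, the
genetic relationship matrix (GRM) `G`, covariates `C` (age, sex, ancestry
PCs) with fixed effects β, and `h² = σg²/(σg² + σe²)` estimated by REML.

`heritcomp` solves the *inverse* problem: given a feature matrix `X`
(subjects × clinical variables), find weights `w` so that the trait
`y = Xw` makes the ideal variance components (σg² = 1, σe² = 0) as likely
as possible. Maximizing the restricted likelihood at those values over `w`,
with an L1 penalty against overfitting, gives

```
min_w  (1/n) wᵀ(XᵀPX)w + (λ/d)‖w‖₁    s.t.  wᵀ(XᵀQX)w = 1
P = G⁻¹ − G⁻¹C(CᵀG⁻¹C)⁻¹CᵀG⁻¹,        Q = JᵀJ/n,  J = I − C(CᵀG⁻¹C)⁻¹CᵀG⁻¹
```

where the constraint fixes the covariate-corrected sample variance of the
trait at 1. The problem is solved by a sequential quadratic programming
(SQP) algorithm after splitting `w = u − v` (u, v ≥ 0) to linearize the L1
norm; λ is tuned by repeated k-fold cross-validated held-out heritability.
At λ = 0 the problem is a generalized Rayleigh-quotient minimization, and
the solver provably agrees with a generalized eigendecomposition.

## Worked example

Simulate a cohort in which five features carry an implanted heritable
component (h² = 0.8, weights [0.22, 0.67, 0.60, 0.30, 0.22]) next to five
pure-noise features, fit the component on the discovery cohort, and measure
the derived trait's chip h² on an independent validation cohort:

```python
import numpy as np
from heritcomp import (HeritableComponentAnalysis, RemlHeritability,
                       SimulationConfig, simulate_setting, equal_weight_trait)

cfg = SimulationConfig(seed=1, n=600, m=800, n_irrelevant=5)
discovery, validation = simulate_setting(cfg)

hca = HeritableComponentAnalysis(penalty=0.004).fit(
    discovery.X, grm=discovery.grm, covariates=discovery.covariates)
print("learned weights:", np.round(hca.w_, 3))

reml = RemlHeritability().fit(validation.X @ hca.w_, validation.grm,
                              covariates=validation.covariates)
print(f"validation chip h2 of the derived trait: {reml.h2_:.3f}")

count = equal_weight_trait(validation.X)
reml_c = RemlHeritability().fit(count, validation.grm,
                                covariates=validation.covariates)
print(f"validation chip h2 of the equal-weight trait: {reml_c.h2_:.3f}")
```

Output:

```
learned weights: [ 0.257  0.615  0.645  0.327  0.217  0.063 -0.042 -0.031 -0.007 -0.049]
validation chip h2 of the derived trait: 0.824
validation chip h2 of the equal-weight trait: 0.512
```

The learned weights recover the implanted direction (the five relevant
features dominate; the noise features get near-zero weights), the derived
trait re-estimates close to the implanted h² of 0.8 on unseen subjects, and
it is far more heritable than the conventional equal-weight "symptom count"
comparator (0.51).

## Command line

The same pipeline is available as subcommands operating on TSV / PLINK /
GCTA-format files:

```
heritcomp simulate --setting 1 --n 1752 --m 2000 --seed 1 --out sim/
heritcomp grm      --genotypes geno.tsv --prune-threshold 0.025 --pcs 3 --out mygrm
heritcomp reml     --trait trait.tsv --covariates cov.tsv --grm mygrm --out reml.json
heritcomp cv       --features X.tsv --covariates cov.tsv --grm mygrm \
                   --grid 0:0.04:0.002 --folds 3 --repeats 10 --seed 1 --out cvout
heritcomp fit      --features X.tsv --covariates cov.tsv --grm mygrm \
                   --lambda 0.004 --out-model model.json --out-scores scores.tsv
heritcomp score    --model model.json --features Xnew.tsv --out scores.tsv
```

Every run writes a provenance block (tool version, parameters, seed) into
its output so any reported number can be reproduced.

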