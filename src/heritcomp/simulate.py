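"""Synthetic cohorts with implanted heritable components.

Genotypes are independent biallelic loci: per-marker reference-allele
frequencies f_j drawn uniformly from a MAF range, counts r_ij ~ Binomial(2,
f_j).  A heritable feature with target heritability h2 is x = Zu + eps with
per-marker effects u_j ~ N(0,1) and residuals eps_i ~ N(0, var(Zu)(1/h2 - 1)),
so the realized genetic:residual variance ratio matches h2 by construction.

Two experimental settings:

* Setting 1 (no covariate effects): four features at h2 = 0.2, a composite
  trait y1 at h2 = 0.8 simulated by the same procedure, and a fifth feature
  solved from the implanted weights w so that X[:, :5] w == y1 exactly;
  irrelevant features are pure N(0,1) noise.
* Setting 2: the five relevant features additionally carry fixed covariate
  effects C beta (sex, age), which propagate to the composite through the
  weight identity; irrelevant features are covariate-only (C beta + noise).

The GRM handed to downstream analyses is built from the causal markers
themselves, mirroring the practice of estimating simulated-trait
heritability on the known causal variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .genotype import (
    GeneticRelationshipMatrix,
    RawGenotypeMatrix,
    StandardizedGenotypeMatrix,
    compute_grm,
    standardize_genotypes,
)

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_genotypes",
    "simulate_heritable_feature",
    "simulate_noise_feature",
    "simulate_covariate_feature",
    "simulate_setting",
]

DEFAULT_W_TRUE = (0.22, 0.67, 0.60, 0.30, 0.22)
DEFAULT_BETA_TRUE = (0.2, 0.5)


@dataclass
class SimulationConfig:
    """Study conditions for a simulated cohort."""

    seed: int
    n: int = 1752
    m: int = 2000
    maf_range: Tuple[float, float] = (0.05, 0.5)
    h2_feature: float = 0.2
    h2_trait: float = 0.8
    w_true: Sequence[float] = DEFAULT_W_TRUE
    n_irrelevant: int = 0
    beta_true: Sequence[float] = DEFAULT_BETA_TRUE
    setting: int = 1

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not (0.0 < self.h2_feature <= 1.0 and 0.0 < self.h2_trait <= 1.0):
            raise ValueError("target h2 must lie in (0, 1]")
        self.w_true = np.asarray(self.w_true, dtype=float)
        if self.w_true.shape != (5,) or self.w_true[4] == 0.0:
            raise ValueError("w_true must have length 5 with w_true[4] != 0")
        self.beta_true = np.asarray(self.beta_true, dtype=float)
        if self.setting not in (1, 2):
            raise ValueError("setting must be 1 or 2")
        if self.n_irrelevant < 0:
            raise ValueError("n_irrelevant must be >= 0")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be within (0, 0.5]")


@dataclass
class SimulatedDataset:
    """One simulated cohort: genotypes, GRM, features, truth."""

    genotypes: RawGenotypeMatrix
    Z: StandardizedGenotypeMatrix
    grm: GeneticRelationshipMatrix
    X: np.ndarray  # relevant features first, then irrelevant
    feature_names: list
    y_true: np.ndarray
    covariates: np.ndarray  # [sex, age]; no intercept column
    covariate_names: list
    w_true: np.ndarray
    beta_true: np.ndarray
    feature_info: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]


def _rng(seed_or_rng):
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_genotypes(n: int, m: int, maf_range=(0.05, 0.5), seed=None
                       ) -> RawGenotypeMatrix:
    """Independent binomial genotypes with per-marker uniform frequencies."""
    if n < 1 or m < 1:
        raise ValueError("n and m must be >= 1")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must be within (0, 0.5]")
    rng = _rng(seed)
    f = rng.uniform(lo, hi, size=m)
    counts = rng.binomial(2, f, size=(n, m)).astype(float)
    return RawGenotypeMatrix(counts=counts)


def simulate_heritable_feature(Z: StandardizedGenotypeMatrix, h2: float,
                               seed=None, unit_variance: bool = True):
    """A feature x = (genetic values) + eps with target heritability h2.

    Genetic values are Zu with per-marker effects u ~ N(0,1); residuals are
    drawn with var(eps) = var(Zu)(1/h2 - 1), which pins the realized
    genetic:residual variance ratio at h2 : (1 - h2).  With ``unit_variance``
    (the default) the genetic values are first rescaled to sample variance
    h2, so the feature has total variance ~1 — heritability is invariant to
    this overall scale, and it puts features on a scale where covariate
    effects of a few tenths are meaningful.  ``unit_variance=False`` keeps
    the raw Zu scale (variance ~m).

    Returns ``(x, info)`` where info records the realized genetic and
    residual sample variances.  h2 = 0 is not admissible here; use
    :func:`simulate_noise_feature` for features without genetic effects.
    """
    if not 0.0 < h2 <= 1.0:
        raise ValueError("h2 must lie in (0, 1]; use simulate_noise_feature "
                         "for h2 = 0")
    rng = _rng(seed)
    u = rng.standard_normal(Z.m)
    g = Z.Z @ u
    if unit_variance:
        g = g * (np.sqrt(h2) / g.std())
    var_g = g.var()
    if h2 == 1.0:
        eps = np.zeros(Z.n)
    else:
        eps = rng.normal(0.0, np.sqrt(var_g * (1.0 / h2 - 1.0)), size=Z.n)
    info = {"h2_target": h2, "var_genetic": float(var_g),
            "var_residual": float(eps.var())}
    return g + eps, info


def simulate_noise_feature(n: int, seed=None) -> np.ndarray:
    """A feature with no genetic effect: standard normal residuals only."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return _rng(seed).standard_normal(n)


def simulate_covariate_feature(C: np.ndarray, beta_true, seed=None,
                               noise_scale: float = 1.0) -> np.ndarray:
    """A covariate-only feature C beta + eps (eps ~ N(0, noise_scale^2)).

    ``noise_scale = 0`` suppresses the residual, leaving the feature exactly
    in the column space of C (useful for checks).
    """
    C = np.atleast_2d(np.asarray(C, dtype=float))
    beta_true = np.asarray(beta_true, dtype=float)
    base = C @ beta_true
    if noise_scale == 0.0:
        return base
    return base + _rng(seed).normal(0.0, noise_scale, size=C.shape[0])


def _simulate_covariates(n, rng):
    sex = rng.binomial(1, 0.5, size=n).astype(float)
    age = rng.normal(40.0, 10.0, size=n)
    age = (age - age.mean()) / age.std()
    return np.column_stack([sex, age])


def _simulate_one(config: SimulationConfig, ss: np.random.SeedSequence
                  ) -> SimulatedDataset:
    rng = np.random.default_rng(ss)
    raw = simulate_genotypes(config.n, config.m, config.maf_range, rng)
    raw = raw.drop_monomorphic()  # rare at these sample sizes, but possible
    Z = standardize_genotypes(raw)
    grm = compute_grm(Z)
    C = _simulate_covariates(config.n, rng)

    feats = []
    infos = []
    for _ in range(4):
        x, info = simulate_heritable_feature(Z, config.h2_feature, rng)
        feats.append(x)
        infos.append(info)
    y1, _ = simulate_heritable_feature(Z, config.h2_trait, rng)
    w = config.w_true
    x5 = (y1 - sum(w[i] * feats[i] for i in range(4))) / w[4]
    feats.append(x5)
    infos.append({"h2_target": None, "derived_from": "weight identity"})

    X = np.column_stack(feats)
    if config.setting == 2:
        shift = C @ config.beta_true
        X = X + shift[:, None]
    # the composite trait via the weight identity; in Setting 2 this equals
    # y1 + sum(w) * C beta since every relevant feature carries the shift
    y_true = X @ w

    for _ in range(config.n_irrelevant):
        if config.setting == 1:
            X = np.column_stack([X, simulate_noise_feature(config.n, rng)])
        else:
            X = np.column_stack(
                [X, simulate_covariate_feature(C, config.beta_true, rng)]
            )
        infos.append({"h2_target": 0.0})

    names = [f"x{j + 1}" for j in range(5)] + [
        f"noise{j + 1}" for j in range(config.n_irrelevant)
    ]
    return SimulatedDataset(
        genotypes=raw, Z=Z, grm=grm, X=X, feature_names=names,
        y_true=y_true, covariates=C, covariate_names=["sex", "age"],
        w_true=w.copy(), beta_true=config.beta_true.copy(),
        feature_info=infos,
    )


def simulate_covariate_effect_replicate(
    seed, n: int = 1752, m: int = 2000, h2: float = 0.2,
    beta_true=DEFAULT_BETA_TRUE, maf_range=(0.05, 0.5),
):
    """One Setting-2-style relevant feature for covariate-recovery studies.

    Returns ``(x, C, grm)``: a heritable feature with fixed effects
    C beta_true added (C = [sex, age], no intercept), and the causal-marker
    GRM.  All randomness derives from ``seed``.
    """
    rng = _rng(seed)
    raw = simulate_genotypes(n, m, maf_range, rng).drop_monomorphic()
    Z = standardize_genotypes(raw)
    grm = compute_grm(Z)
    C = _simulate_covariates(n, rng)
    x, _ = simulate_heritable_feature(Z, h2, rng)
    return x + C @ np.asarray(beta_true, dtype=float), C, grm


def simulate_setting(config: SimulationConfig):
    """Generate a (discovery, validation) pair from disjoint sub-seeds."""
    ss_disc, ss_val = np.random.SeedSequence(config.seed).spawn(2)
    return _simulate_one(config, ss_disc), _simulate_one(config, ss_val)
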