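"""Restricted maximum likelihood (REML) for the one-GRM mixed model.

Model:  y = C beta + g + eps,   g ~ N(0, G sigma_g^2),  eps ~ N(0, I sigma_e^2),

so Cov(y) = Omega = G sigma_g^2 + I sigma_e^2.  The restricted log-likelihood
(constants dropped) is

    l2 = -1/2 ( ln|Omega| + ln|C' Omega^-1 C| + y' P y ),
    P  = Omega^-1 - Omega^-1 C (C' Omega^-1 C)^-1 C' Omega^-1,

and chip heritability is h^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2).

Fitting strategy: eigendecompose G = U D U' once, reparameterize by
(h^2, sigma_p^2) with Omega = sigma_p^2 (h^2 G + (1-h^2) I), profile
sigma_p^2 out in closed form, and maximize the resulting one-dimensional
profile likelihood over h^2 in [0, 1) by a grid scan plus bounded scalar
refinement.  Several traits sharing one GRM can reuse the eigendecomposition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import linalg, optimize
from sklearn.base import BaseEstimator

from .genotype import GeneticRelationshipMatrix

__all__ = [
    "MixedModelDesign",
    "VarianceComponents",
    "restricted_loglik",
    "reml_fit",
    "estimate_fixed_effects",
    "chip_heritability",
    "RemlHeritability",
]

_H2_CAP = 1.0 - 1e-6  # interior upper bound for the profile search
_BOUNDARY_TOL = 1e-5  # estimates this close to 0/1 are reported on the boundary


@dataclass
class MixedModelDesign:
    """Aligned trait vector, covariate matrix (with intercept), and GRM."""

    y: np.ndarray
    C: np.ndarray
    grm: GeneticRelationshipMatrix

    def __post_init__(self):
        y = np.asarray(self.y, dtype=float).ravel()
        C = np.atleast_2d(np.asarray(self.C, dtype=float))
        if C.shape[0] != y.shape[0]:
            C = C.T
        n = y.shape[0]
        if C.shape[0] != n or self.grm.n != n:
            raise ValueError("y, C and G must agree on the number of subjects")
        p = C.shape[1]
        if n < p + 2:
            raise ValueError(f"need n >= p + 2 (n={n}, p={p})")
        if np.linalg.matrix_rank(C) < p:
            raise ValueError("covariate matrix C is rank deficient")
        self.y, self.C = y, C

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def p(self) -> int:
        return self.C.shape[1]


@dataclass
class VarianceComponents:
    """REML variance components and derived chip heritability."""

    sigma_g2: float
    sigma_e2: float
    sigma_p2: float
    h2: float
    loglik: float
    beta: np.ndarray
    se_h2: Optional[float] = None
    boundary: bool = False

    def __post_init__(self):
        if not np.isfinite(self.loglik):
            raise ValueError("loglik must be finite")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")


def _omega_factor(grm, sigma_g2, sigma_e2):
    n = grm.n
    omega = sigma_g2 * grm.G + sigma_e2 * np.eye(n)
    try:
        return linalg.cho_factor(omega, lower=True)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "Omega = G*sigma_g2 + I*sigma_e2 is singular or indefinite"
        ) from exc


def restricted_loglik(
    design: MixedModelDesign, sigma_g2: float, sigma_e2: float
) -> float:
    """Evaluate l2 at the given variance components (constants dropped)."""
    if sigma_g2 < 0 or sigma_e2 < 0:
        raise ValueError("variance components must be non-negative")
    cf = _omega_factor(design.grm, sigma_g2, sigma_e2)
    logdet_omega = 2.0 * np.sum(np.log(np.diag(cf[0])))
    oi_y = linalg.cho_solve(cf, design.y)
    oi_C = linalg.cho_solve(cf, design.C)
    M = design.C.T @ oi_C
    try:
        mf = linalg.cho_factor(M, lower=True)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("C' Omega^-1 C is rank deficient") from exc
    logdet_M = 2.0 * np.sum(np.log(np.diag(mf[0])))
    b = design.C.T @ oi_y
    ypy = design.y @ oi_y - b @ linalg.cho_solve(mf, b)
    return -0.5 * (logdet_omega + logdet_M + ypy)


def _grm_eig(grm: GeneticRelationshipMatrix):
    d, U = linalg.eigh(grm.G)
    scale = max(1.0, d[-1])
    if d[0] < -1e-8 * scale:
        raise ValueError(
            f"G is not positive semidefinite (min eigenvalue {d[0]:.3e})"
        )
    return np.maximum(d, 0.0), U


class _Profile:
    """Profile restricted log-likelihood over h2 in the rotated basis."""

    def __init__(self, design, eig):
        d, U = eig
        self.d = d
        self.yt = U.T @ design.y
        self.Ct = U.T @ design.C
        self.n = design.n
        self.p = design.p

    def parts(self, h2):
        t = h2 * self.d + (1.0 - h2)
        w = 1.0 / t
        Cw = self.Ct * w[:, None]
        M = self.Ct.T @ Cw
        mf = linalg.cho_factor(M, lower=True)
        b = Cw.T @ self.yt
        q = self.yt @ (w * self.yt) - b @ linalg.cho_solve(mf, b)
        logdet_t = np.sum(np.log(t))
        logdet_M = 2.0 * np.sum(np.log(np.diag(mf[0])))
        return q, logdet_t, logdet_M, mf, Cw

    def loglik(self, h2):
        q, logdet_t, logdet_M, _, _ = self.parts(h2)
        np_ = self.n - self.p
        if q <= 0:
            return -np.inf
        return -0.5 * (np_ * (np.log(q / np_) + 1.0) + logdet_t + logdet_M)

    def sigma_p2(self, h2):
        q = self.parts(h2)[0]
        return q / (self.n - self.p)

    def beta(self, h2):
        _, _, _, mf, Cw = self.parts(h2)
        return linalg.cho_solve(mf, Cw.T @ self.yt)


def reml_fit(
    design: MixedModelDesign,
    eig=None,
    compute_se: bool = False,
    grid_points: int = 51,
) -> VarianceComponents:
    """Maximize l2 over (sigma_g2, sigma_e2) and report the components.

    ``eig`` may carry a precomputed ``scipy.linalg.eigh`` decomposition of G
    (eigenvalues ascending, eigenvectors as columns) to amortize the O(n^3)
    factorization across traits sharing one GRM.
    """
    G = design.grm.G
    n = design.n
    if np.linalg.norm(G - np.eye(n), "fro") / np.sqrt(n) < 1e-6:
        raise ValueError(
            "G is numerically the identity: sigma_g2 and sigma_e2 are "
            "confounded and h2 is unidentifiable"
        )
    if eig is None:
        eig = _grm_eig(design.grm)
    prof = _Profile(design, eig)

    grid = np.linspace(0.0, _H2_CAP, grid_points)
    vals = np.array([prof.loglik(h) for h in grid])
    i = int(np.argmax(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid_points - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda h: -prof.loglik(h),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-8},
        )
        h_hat = float(res.x)
        if prof.loglik(h_hat) < vals[i]:
            h_hat = float(grid[i])
    else:
        h_hat = float(grid[i])

    loglik = prof.loglik(h_hat)
    sp2 = prof.sigma_p2(h_hat)
    beta = prof.beta(h_hat)

    boundary = h_hat <= _BOUNDARY_TOL or h_hat >= 1.0 - _BOUNDARY_TOL
    h2_report = 0.0 if h_hat <= _BOUNDARY_TOL else (
        1.0 if h_hat >= 1.0 - _BOUNDARY_TOL else h_hat
    )
    sg2 = h2_report * sp2
    se2 = sp2 - sg2

    se_h2 = None
    if compute_se:
        se_h2 = _profile_se(prof, h_hat)

    return VarianceComponents(
        sigma_g2=sg2,
        sigma_e2=se2,
        sigma_p2=sp2,
        h2=h2_report,
        loglik=loglik,
        beta=beta,
        se_h2=se_h2,
        boundary=boundary,
    )


def _profile_se(prof, h_hat, step=1e-3):
    """SE of h2 from the curvature of the profile likelihood (central differences)."""
    lo = max(h_hat - step, 0.0)
    hi = min(h_hat + step, _H2_CAP)
    if hi - lo < step:  # too close to a boundary for a central difference
        return None
    mid = 0.5 * (lo + hi)
    d2 = (prof.loglik(hi) - 2.0 * prof.loglik(mid) + prof.loglik(lo)) / (
        (0.5 * (hi - lo)) ** 2
    )
    if d2 >= 0:
        return None
    return float(1.0 / np.sqrt(-d2))


def estimate_fixed_effects(
    design: MixedModelDesign, vc: VarianceComponents
) -> np.ndarray:
    """GLS fixed effects beta = (C' Omega^-1 C)^-1 C' Omega^-1 y at the fitted Omega."""
    sg2, se2 = vc.sigma_g2, vc.sigma_e2
    if se2 == 0.0:
        se2 = max(vc.sigma_p2, 1.0) * 1e-8  # keep Omega invertible at the boundary
    cf = _omega_factor(design.grm, sg2, se2)
    oi_C = linalg.cho_solve(cf, design.C)
    M = design.C.T @ oi_C
    try:
        mf = linalg.cho_factor(M, lower=True)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("C' Omega^-1 C is rank deficient") from exc
    return linalg.cho_solve(mf, oi_C.T @ design.y)


def chip_heritability(vc: VarianceComponents) -> float:
    """h^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2)."""
    if vc.sigma_p2 <= 0:
        raise ValueError("total phenotypic variance is zero; h2 undefined")
    return vc.sigma_g2 / vc.sigma_p2


class RemlHeritability(BaseEstimator):
    """Chip-heritability estimator for a quantitative trait.

    Parameters
    ----------
    compute_se : bool, default False
        Also report a standard error for h2 from the profile-likelihood
        curvature.
    grid_points : int, default 51
        Resolution of the initial h2 grid scan before bounded refinement.

    Attributes (after ``fit``)
    --------------------------
    sigma_g2_, sigma_e2_, sigma_p2_, h2_, beta_, loglik_, se_h2_, boundary_
    """

    def __init__(self, compute_se: bool = False, grid_points: int = 51):
        self.compute_se = compute_se
        self.grid_points = grid_points

    def fit(self, y, grm, covariates=None, eig=None):
        if not isinstance(grm, GeneticRelationshipMatrix):
            grm = GeneticRelationshipMatrix(G=np.asarray(grm, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        C = _with_intercept(covariates, y.shape[0])
        design = MixedModelDesign(y=y, C=C, grm=grm)
        vc = reml_fit(
            design, eig=eig, compute_se=self.compute_se,
            grid_points=self.grid_points,
        )
        self.variance_components_ = vc
        self.sigma_g2_ = vc.sigma_g2
        self.sigma_e2_ = vc.sigma_e2
        self.sigma_p2_ = vc.sigma_p2
        self.h2_ = vc.h2
        self.beta_ = vc.beta
        self.loglik_ = vc.loglik
        self.se_h2_ = vc.se_h2
        self.boundary_ = vc.boundary
        return self


def _with_intercept(covariates, n):
    """Covariate matrix with an intercept column ensured (prepended if absent)."""
    if covariates is None:
        return np.ones((n, 1))
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] != n:
        C = C.T
    has_const = any(np.ptp(C[:, j]) == 0 and C[0, j] != 0 for j in range(C.shape[1]))
    if not has_const:
        C = np.column_stack([np.ones(n), C])
    return C
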