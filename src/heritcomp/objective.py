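"""Fixed matrices of the inverse-heritability problem.

Setting the variance components to their ideal values (sigma_g2 = 1,
sigma_e2 = 0) turns the covariance Omega into the GRM G itself, and the
restricted log-likelihood of a candidate trait y = Xw into a quadratic form.
Two n x n matrices capture it:

    P = G^-1 - G^-1 C (C' G^-1 C)^-1 C' G^-1      (objective;  P C = 0)
    J = I - C (C' G^-1 C)^-1 C' G^-1,  Q = J'J/n  (constraint; Q C = 0)

The optimization then reads: minimize (1/n) w' X'PX w subject to
w' X'QX w = 1, the latter fixing the covariate-corrected sample variance of
the trait to one.  ``A = X'PX/n`` and ``B = X'QX`` are the d x d forms the
optimizer consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import linalg
from sklearn.preprocessing import MinMaxScaler

from .genotype import GeneticRelationshipMatrix

__all__ = [
    "PhenotypeFeatureMatrix",
    "ObjectiveMatrices",
    "normalize_features",
    "build_projection_P",
    "build_Q",
    "build_quadratic_forms",
    "build_objective",
    "ensure_intercept",
]

logger = logging.getLogger(__name__)


@dataclass
class PhenotypeFeatureMatrix:
    """Clinical feature matrix with optional record of [0,1] min-max scaling."""

    X: np.ndarray
    feature_names: Sequence[str] = None
    data_min: Optional[np.ndarray] = None  # per-feature raw minima, if scaled
    data_max: Optional[np.ndarray] = None

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 1:
            raise ValueError("X must be 2-D with at least one feature")
        if np.isnan(X).any():
            raise ValueError("X contains missing values; handle them upstream")
        self.X = X
        if self.feature_names is None:
            self.feature_names = [f"x{j + 1}" for j in range(X.shape[1])]
        self.feature_names = list(self.feature_names)
        if len(self.feature_names) != X.shape[1]:
            raise ValueError("feature_names length mismatch")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    @property
    def normalized(self) -> bool:
        return self.data_min is not None

    def apply_normalization(self, X_raw: np.ndarray) -> np.ndarray:
        """Map new raw observations through the training min-max affine map."""
        if not self.normalized:
            return np.asarray(X_raw, dtype=float)
        X_raw = np.asarray(X_raw, dtype=float)
        return (X_raw - self.data_min) / (self.data_max - self.data_min)

    def invert_normalization(self, X_scaled: np.ndarray) -> np.ndarray:
        if not self.normalized:
            return np.asarray(X_scaled, dtype=float)
        return np.asarray(X_scaled, dtype=float) * (
            self.data_max - self.data_min
        ) + self.data_min


def normalize_features(X_raw, feature_names=None) -> PhenotypeFeatureMatrix:
    """Min-max scale each feature to [0, 1], keeping the affine map for scoring.

    A constant feature has no admissible scaling and raises, naming it.
    """
    X_raw = np.asarray(X_raw, dtype=float)
    if X_raw.ndim != 2:
        raise ValueError("X must be 2-D")
    if feature_names is None:
        feature_names = [f"x{j + 1}" for j in range(X_raw.shape[1])]
    span = np.ptp(X_raw, axis=0)
    if (span == 0).any():
        bad = [feature_names[j] for j in np.flatnonzero(span == 0)]
        raise ValueError(f"constant feature(s) cannot be normalized: {bad}")
    scaler = MinMaxScaler().fit(X_raw)
    # clip float round-off overshoot (e.g. 1 + 2e-16) back into [0, 1]
    return PhenotypeFeatureMatrix(
        X=np.clip(scaler.transform(X_raw), 0.0, 1.0),
        feature_names=feature_names,
        data_min=scaler.data_min_.copy(),
        data_max=scaler.data_max_.copy(),
    )


@dataclass
class ObjectiveMatrices:
    """P, Q and the feature-space quadratic forms A = X'PX/n, B = X'QX."""

    P: np.ndarray
    Q: np.ndarray
    A: np.ndarray
    B: np.ndarray


def _factor_with_ridge(G: np.ndarray):
    """Cholesky of G with an escalating relative ridge; GRMs from finite marker
    panels are routinely near-singular."""
    n = G.shape[0]
    base = np.trace(G) / n
    for rel in (1e-8, 1e-7, 1e-6, 1e-5, 1e-4):
        try:
            return linalg.cho_factor(G + rel * base * np.eye(n), lower=True)
        except linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError(
        "G could not be factorized even with ridge 1e-4 * trace(G)/n"
    )


def _check_covariates(C, n):
    if C is None:
        return None
    C = np.atleast_2d(np.asarray(C, dtype=float))
    if C.shape[0] != n:
        C = C.T
    if C.shape[0] != n:
        raise ValueError("covariate matrix row count does not match subjects")
    if C.shape[1] == 0:
        return None
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ValueError("covariate matrix is collinear (rank deficient)")
    return C


def ensure_intercept(C, n):
    """Prepend an intercept column unless one (a nonzero constant) is present."""
    if C is None:
        return np.ones((n, 1))
    C = _check_covariates(C, n)
    has_const = any(
        np.ptp(C[:, j]) == 0 and C[0, j] != 0 for j in range(C.shape[1])
    )
    if not has_const:
        logger.info("adding an intercept column to the covariate matrix")
        C = np.column_stack([np.ones(n), C])
    return C


def build_projection_P(grm: GeneticRelationshipMatrix, C=None) -> np.ndarray:
    """P = G^-1 - G^-1 C (C'G^-1 C)^-1 C'G^-1; with no covariates, P = G^-1."""
    G = grm.G
    n = grm.n
    cf = _factor_with_ridge(G)
    Ginv = linalg.cho_solve(cf, np.eye(n))
    C = _check_covariates(C, n)
    if C is None:
        P = Ginv
    else:
        GiC = linalg.cho_solve(cf, C)
        M = C.T @ GiC
        mf = linalg.cho_factor(M, lower=True)
        P = Ginv - GiC @ linalg.cho_solve(mf, GiC.T)
    return (P + P.T) / 2.0


def build_Q(grm: GeneticRelationshipMatrix, C=None) -> np.ndarray:
    """Q = J'J/n with J = I - C (C'G^-1 C)^-1 C'G^-1; no covariates gives I/n."""
    n = grm.n
    C = _check_covariates(C, n)
    if C is None:
        return np.eye(n) / n
    cf = _factor_with_ridge(grm.G)
    GiC = linalg.cho_solve(cf, C)
    M = C.T @ GiC
    mf = linalg.cho_factor(M, lower=True)
    J = np.eye(n) - C @ linalg.cho_solve(mf, GiC.T)
    Q = J.T @ J / n
    return (Q + Q.T) / 2.0


def build_quadratic_forms(X, P: np.ndarray, Q: np.ndarray) -> ObjectiveMatrices:
    """A = X'PX/n and B = X'QX, symmetrized against round-off asymmetry."""
    Xm = X.X if isinstance(X, PhenotypeFeatureMatrix) else np.asarray(X, float)
    n = Xm.shape[0]
    if P.shape != (n, n) or Q.shape != (n, n):
        raise ValueError(
            f"P/Q must be {n}x{n} to match X with {n} subjects; "
            f"got {P.shape} and {Q.shape}"
        )
    A = Xm.T @ P @ Xm / n
    B = Xm.T @ Q @ Xm
    return ObjectiveMatrices(P=P, Q=Q, A=(A + A.T) / 2.0, B=(B + B.T) / 2.0)


def build_objective(X, grm: GeneticRelationshipMatrix, C=None) -> ObjectiveMatrices:
    """Convenience: P, Q, A, B in one pass for a feature matrix, GRM and covariates."""
    P = build_projection_P(grm, C)
    Q = build_Q(grm, C)
    return build_quadratic_forms(X, P, Q)
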