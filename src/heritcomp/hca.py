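"""Heritable component analysis as a scikit-learn style transformer."""

from __future__ import annotations

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator, TransformerMixin

from .genotype import GeneticRelationshipMatrix
from .objective import (
    PhenotypeFeatureMatrix,
    build_objective,
    ensure_intercept,
)
from .sqp import score_subjects, solve, split_variables

__all__ = ["HeritableComponentAnalysis"]


class HeritableComponentAnalysis(TransformerMixin, BaseEstimator):
    """Learn a sparse linear combination of clinical features whose composite
    trait maximizes chip heritability.

    Solves  min_w (1/n) w'X'PX w + (penalty/d) ||w||_1  s.t.  w'X'QX w = 1,
    where P and Q are projections built from the genetic relationship matrix
    and covariates with the variance components pinned at their ideal values
    (genetic variance 1, residual 0).  The penalty controls sparsity of w and
    is typically tuned by cross-validated held-out heritability.

    Parameters
    ----------
    penalty : float, default 0.0
        L1 regularization weight (the lambda of the objective; scaled by 1/d
        internally).
    max_iter, tol, feas_tol : SQP stopping controls (KKT residual and
        equality-constraint tolerance).
    multi_start : int, default 0
        Extra seeded restarts of the non-convex solver; best KKT point wins.
    random_state : seed for the restarts (unused when multi_start == 0).

    Attributes
    ----------
    w_ : (d,) learned weights, canonical sign, exact zeros below 1e-8.
    beta_ : covariate coefficients of the derived trait at Omega = G.
    objective_value_, constraint_residual_, converged_, n_iter_ : diagnostics.
    model_ : the full :class:`~heritcomp.sqp.TraitModel`.
    """

    def __init__(
        self,
        penalty: float = 0.0,
        max_iter: int = 500,
        tol: float = 1e-6,
        feas_tol: float = 1e-8,
        multi_start: int = 0,
        random_state=None,
    ):
        self.penalty = penalty
        self.max_iter = max_iter
        self.tol = tol
        self.feas_tol = feas_tol
        self.multi_start = multi_start
        self.random_state = random_state

    def fit(self, X, y=None, *, grm, covariates=None):
        """Fit on a feature matrix (subjects x features), GRM and covariates.

        ``X`` may be a raw array or a :class:`PhenotypeFeatureMatrix`; an
        intercept column is ensured in the covariates.
        """
        if not isinstance(grm, GeneticRelationshipMatrix):
            grm = GeneticRelationshipMatrix(G=np.asarray(grm, dtype=float))
        pfm = X if isinstance(X, PhenotypeFeatureMatrix) else None
        Xm = pfm.X if pfm is not None else np.asarray(X, dtype=float)
        if Xm.shape[0] != grm.n:
            raise ValueError("X and G must have the same number of subjects")
        C = ensure_intercept(covariates, Xm.shape[0])

        om = build_objective(Xm, grm, C)
        sp = split_variables(om.A, om.B, self.penalty)
        model = solve(
            sp,
            max_iter=self.max_iter,
            tol=self.tol,
            feas_tol=self.feas_tol,
            multi_start=self.multi_start,
            seed=self.random_state,
        )

        # covariate coefficients of the derived trait at Omega = G
        trait = Xm @ model.w
        cf = linalg.cho_factor(
            grm.G + 1e-8 * (np.trace(grm.G) / grm.n) * np.eye(grm.n),
            lower=True,
        )
        GiC = linalg.cho_solve(cf, C)
        beta = linalg.solve(C.T @ GiC, GiC.T @ trait, assume_a="pos")
        model.beta = beta
        if pfm is not None:
            model.feature_names = list(pfm.feature_names)
            model.data_min = pfm.data_min
            model.data_max = pfm.data_max

        self.model_ = model
        self.w_ = model.w
        self.beta_ = beta
        self.objective_value_ = model.objective_value
        self.constraint_residual_ = model.constraint_residual
        self.converged_ = model.converged
        self.n_iter_ = model.n_iter
        self.n_features_in_ = Xm.shape[1]
        return self

    def transform(self, X):
        """Score subjects: y = Xw (training normalization applied to raw input)."""
        if not hasattr(self, "model_"):
            raise RuntimeError("fit must be called before transform")
        return score_subjects(self.model_, X)
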