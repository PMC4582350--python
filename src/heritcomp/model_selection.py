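"""Penalty tuning and trait evaluation by cross-validated heritability.

The tuning protocol is repeated k-fold CV: for each penalty value, fit the
component on the training folds (the projection matrices P and Q are rebuilt
from the training-subject block of the GRM), score the held-out subjects,
and estimate the held-out trait's chip heritability by REML on the held-out
GRM block.  The chosen penalty maximizes the mean held-out h2 (ties go to
the smallest penalty).  The evaluation protocol re-estimates a fitted
trait's h2 on repeated random subject subsamples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import linalg

from .genotype import GeneticRelationshipMatrix
from .hca import HeritableComponentAnalysis
from .objective import ensure_intercept
from .reml import MixedModelDesign, reml_fit
from .sqp import TraitModel, score_subjects

__all__ = [
    "CVReport",
    "cv_tune",
    "evaluation_cv",
    "equal_weight_trait",
    "model_error_metrics",
]


@dataclass
class CVReport:
    """Held-out heritability per penalty value across folds and repeats."""

    lambda_grid: np.ndarray
    h2_values: np.ndarray  # (n_lambda, repeats * folds); NaN = failed fold
    mean: np.ndarray
    median: np.ndarray
    sd: np.ndarray
    chosen_lambda: float
    folds: int
    repeats: int
    seed: Optional[int] = None
    fit_kwargs: dict = field(default_factory=dict)


def _fold_indices(n, folds, rng):
    """Balanced fold assignment from a seeded permutation."""
    perm = rng.permutation(n)
    return [np.sort(perm[k::folds]) for k in range(folds)]


def _heldout_h2(y, C, grm, idx, eig=None):
    design = MixedModelDesign(y=y, C=C[idx], grm=grm.subset(idx))
    return reml_fit(design, eig=eig).h2


def cv_tune(
    X,
    C,
    grm: GeneticRelationshipMatrix,
    lambda_grid: Sequence[float],
    folds: int = 3,
    repeats: int = 10,
    seed: Optional[int] = None,
    **fit_kwargs,
) -> CVReport:
    """Choose the L1 penalty by repeated k-fold cross-validated heritability.

    For every penalty and fold, the model is fit on the training subjects
    only and the held-out subjects' trait h2 is estimated from their own GRM
    block; training and held-out index sets are disjoint by construction.
    REML failures are recorded as NaN with a warning and excluded from the
    per-penalty mean.
    """
    lambda_grid = np.asarray(list(lambda_grid), dtype=float)
    if lambda_grid.size == 0:
        raise ValueError("lambda grid must be non-empty")
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    C = ensure_intercept(C, n)
    p = C.shape[1]
    if n // folds <= p + 10:
        raise ValueError(
            f"folds of ~{n // folds} subjects are too small for REML with "
            f"{p} covariates"
        )
    rng = np.random.default_rng(seed)
    h2 = np.full((lambda_grid.size, repeats * folds), np.nan)

    col = 0
    for _ in range(repeats):
        fold_idx = _fold_indices(n, folds, rng)
        for k in range(folds):
            test = fold_idx[k]
            train = np.sort(np.concatenate(
                [fold_idx[j] for j in range(folds) if j != k]
            ))
            assert np.intersect1d(train, test).size == 0
            grm_test = grm.subset(test)
            eig_test = linalg.eigh(grm_test.G)
            eig_test = (np.maximum(eig_test[0], 0.0), eig_test[1])
            for li, lam in enumerate(lambda_grid):
                est = HeritableComponentAnalysis(penalty=lam, **fit_kwargs)
                est.fit(X[train], grm=grm.subset(train), covariates=C[train])
                y_test = X[test] @ est.w_
                try:
                    h2[li, col] = _heldout_h2(
                        y_test, C, grm, test, eig=eig_test
                    )
                except (ValueError, np.linalg.LinAlgError) as exc:
                    warnings.warn(
                        f"REML failed in a fold (lambda={lam}): {exc}",
                        stacklevel=2,
                    )
            col += 1

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        mean = np.nanmean(h2, axis=1)
        median = np.nanmedian(h2, axis=1)
        sd = np.nanstd(h2, axis=1, ddof=1)
    best = np.nanmax(mean)
    order = np.argsort(lambda_grid, kind="stable")
    chosen = next(
        float(lambda_grid[i]) for i in order if mean[i] >= best - 1e-12
    )
    return CVReport(
        lambda_grid=lambda_grid, h2_values=h2, mean=mean, median=median,
        sd=sd, chosen_lambda=chosen, folds=folds, repeats=repeats, seed=seed,
        fit_kwargs=dict(fit_kwargs),
    )


def evaluation_cv(
    model: TraitModel,
    X,
    C,
    grm: GeneticRelationshipMatrix,
    fraction: float = 2.0 / 3.0,
    repeats: int = 10,
    seed: Optional[int] = None,
):
    """Mean and sd of the fitted trait's h2 over random subject subsamples.

    Each repeat draws ceil(fraction * n) subjects without replacement, scores
    them with the already-fitted model, and re-estimates h2 on their GRM
    block.  Returns ``(mean, sd, values)``.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    C = ensure_intercept(C, n)
    size = int(np.ceil(fraction * n))
    rng = np.random.default_rng(seed)
    vals = np.empty(repeats)
    for r in range(repeats):
        idx = np.sort(rng.choice(n, size=size, replace=False))
        y = score_subjects(model, X[idx])
        vals[r] = _heldout_h2(y, C, grm, idx)
    return float(vals.mean()), float(vals.std(ddof=1) if repeats > 1 else 0.0), vals


def equal_weight_trait(X) -> np.ndarray:
    """The symptom-count comparator: equal-weight sum of all features."""
    return np.asarray(X, dtype=float).sum(axis=1)


def model_error_metrics(w_hat, w_true, y_hat, y_true):
    """Weight and trait recovery errors against the implanted model.

    Sign-aligns the estimate first (the objective is sign-invariant), then
    returns ``SE_w = ||w_true - w_hat||^2`` and the mean squared trait
    residual ``SE_y = mean((y_true - y_hat)^2)``.
    """
    w_hat = np.asarray(w_hat, dtype=float)
    w_true = np.asarray(w_true, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    y_true = np.asarray(y_true, dtype=float)
    if w_hat.shape != w_true.shape or y_hat.shape != y_true.shape:
        raise ValueError("length mismatch between estimates and truth")
    if np.linalg.norm(w_true + w_hat) < np.linalg.norm(w_true - w_hat):
        w_hat = -w_hat
        y_hat = -y_hat
    se_w = float(np.sum((w_true - w_hat) ** 2))
    se_y = float(np.mean((y_true - y_hat) ** 2))
    return se_w, se_y
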