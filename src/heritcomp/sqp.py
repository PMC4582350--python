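"""Sequential quadratic programming for the sparse heritable-component problem.

The trait-refinement problem

    minimize   (1/n) w' X'PX w + (lambda/d) ||w||_1
    subject to w' X'QX w = 1

is made smooth by splitting w = u - v with u, v >= 0.  Writing
gamma = [u; v] and H = [X, -X], both quadratic forms become block forms in
gamma ([[A, -A], [-A, A]] for A = X'PX/n, likewise B = X'QX) and the L1 norm
becomes the linear term (lambda/d) * sum(gamma).  The resulting program has a
quadratic objective, one quadratic equality constraint and sign constraints,
and is solved by SQP: at each iterate a convexified QP with the linearized
equality gives a step direction and multiplier estimates, accepted by
backtracking on the exact-penalty merit f + mu*|g1|.

Initialization follows u = 1, v = 0, alpha = 1; only convergence to a local
minimizer is guaranteed, so an optional seeded multi-start keeps the best KKT
point found.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import linalg
from scipy.optimize import minimize

from .objective import PhenotypeFeatureMatrix

__all__ = [
    "SplitProblem",
    "SQPState",
    "TraitModel",
    "split_variables",
    "qp_subproblem",
    "merit_line_search",
    "solve",
    "score_subjects",
]

_ARMIJO = 1e-4
_S_MIN = 1e-10
_ZERO_W = 1e-8  # coefficients below this are reported as exact zeros


@dataclass
class SplitProblem:
    """Quadratic forms of the split (gamma-space) program."""

    A2: np.ndarray
    B2: np.ndarray
    lin: np.ndarray  # (lambda/d) * 1
    lam: float
    d: int

    @property
    def e(self) -> int:
        """Constraint count: one equality plus 2d sign constraints."""
        return 2 * self.d + 1

    def f(self, gamma):
        return gamma @ self.A2 @ gamma + self.lin @ gamma

    def grad_f(self, gamma):
        return 2.0 * self.A2 @ gamma + self.lin

    def g1(self, gamma):
        return gamma @ self.B2 @ gamma - 1.0

    def grad_g1(self, gamma):
        return 2.0 * self.B2 @ gamma

    def merit(self, gamma, mu_pen):
        return self.f(gamma) + mu_pen * abs(self.g1(gamma))


@dataclass
class SQPState:
    """Iterate of the SQP loop: split variables, multipliers, diagnostics."""

    gamma: np.ndarray
    alpha: np.ndarray  # [equality multiplier, sign-constraint multipliers]
    n_iter: int = 0
    kkt_residual: float = np.inf
    merit_value: float = np.inf
    merit_history: list = field(default_factory=list)
    step_history: list = field(default_factory=list)

    @property
    def u(self):
        d = self.gamma.shape[0] // 2
        return self.gamma[:d]

    @property
    def v(self):
        d = self.gamma.shape[0] // 2
        return self.gamma[d:]


@dataclass
class TraitModel:
    """A fitted sparse linear trait y = Xw with its diagnostics."""

    w: np.ndarray
    lam: float
    objective_value: float
    constraint_residual: float
    converged: bool
    n_iter: int = 0
    kkt_residual: float = np.nan
    beta: Optional[np.ndarray] = None
    feature_names: Optional[list] = None
    data_min: Optional[np.ndarray] = None  # training min-max maps, if any
    data_max: Optional[np.ndarray] = None
    provenance: dict = field(default_factory=dict)


def split_variables(A: np.ndarray, B: np.ndarray, lam: float) -> SplitProblem:
    """Build the 2d-dimensional split program from A = X'PX/n and B = X'QX."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("A and B must be square matrices of equal dimension")
    d = A.shape[0]
    A2 = np.block([[A, -A], [-A, A]])
    B2 = np.block([[B, -B], [-B, B]])
    lin = (lam / d) * np.ones(2 * d)
    return SplitProblem(A2=A2, B2=B2, lin=lin, lam=lam, d=d)


def _convexified_hessian(sp: SplitProblem, alpha1: float, boost: float = 0.0):
    W = 2.0 * (sp.A2 + alpha1 * sp.B2)
    W = (W + W.T) / 2.0
    lam_min = linalg.eigvalsh(W, subset_by_index=(0, 0))[0]
    shift = boost
    if lam_min < 0:
        shift += abs(lam_min) + 1e-8
    if shift > 0:
        W = W + shift * np.eye(W.shape[0])
    return W


def _solve_qp(W, g, a, g1, gamma):
    """min 1/2 p'Wp + g'p  s.t.  a'p + g1 = 0,  p >= -gamma.

    Returns (p, success).  Falls back to an elastic relaxation of the
    equality row if the linearized constraint is incompatible with the bounds
    (standard SQP restoration).
    """
    m = gamma.shape[0]
    bounds = [(-gi, None) for gi in gamma]
    lower = -gamma
    eq_tol = 1e-8 * (1.0 + abs(g1))

    def _usable(p):
        # judge the subsolver's iterate by feasibility, not by its exit
        # status: on degenerate QPs SLSQP can hit its iteration limit while
        # already holding an excellent point; a poor-but-feasible direction
        # is caught later by the merit line search
        if p is None or not np.isfinite(p).all():
            return None
        p = np.maximum(p, lower)
        if abs(a @ p + g1) > eq_tol:
            return None
        return p

    def fun(p):
        Wp = W @ p
        return 0.5 * p @ Wp + g @ p, Wp + g

    cons = [{"type": "eq", "fun": lambda p: a @ p + g1, "jac": lambda p: a}]
    # start from the minimum-norm point on the linearized constraint, clipped
    # to the bounds; SLSQP behaves far better from a near-feasible point
    aa = a @ a
    p0 = np.maximum(-g1 * a / aa, lower) if aa > 1e-300 else np.zeros(m)
    res = minimize(
        fun, p0, jac=True, bounds=bounds, constraints=cons,
        method="SLSQP", options={"maxiter": 300, "ftol": 1e-14},
    )
    p_ok = _usable(res.x)
    if p_ok is not None:
        return p_ok, True

    # elastic mode: a'p + g1 = t+ - t-, penalized slack
    rho = 1e3 * (1.0 + abs(g1) + np.abs(g).max())

    def fun_e(z):
        p, t = z[:m], z[m:]
        Wp = W @ p
        val = 0.5 * p @ Wp + g @ p + rho * t.sum()
        grad = np.concatenate([Wp + g, rho * np.ones(2)])
        return val, grad

    cons_e = [{
        "type": "eq",
        "fun": lambda z: a @ z[:m] + g1 - z[m] + z[m + 1],
        "jac": lambda z: np.concatenate([a, [-1.0, 1.0]]),
    }]
    res_e = minimize(
        fun_e, np.zeros(m + 2), jac=True,
        bounds=bounds + [(0, None), (0, None)],
        constraints=cons_e, method="SLSQP",
        options={"maxiter": 200, "ftol": 1e-14},
    )
    p_e = res_e.x[:m] if res_e.x is not None else None
    if p_e is not None and np.isfinite(p_e).all():
        # elastic steps are usable even when SLSQP reports a weak exit
        # status (e.g. a flat directional derivative at the solution)
        return p_e, True
    if res.x is not None and np.isfinite(res.x).all():
        return res.x, False
    return np.zeros(m), False


def _recover_multipliers(W, g, a, p, gamma):
    """Equality and bound multipliers from QP stationarity on the free set."""
    r = W @ p + g
    tol = 1e-8 * (1.0 + np.abs(gamma).max())
    free = (gamma + p) > tol
    aa = a[free] @ a[free]
    if aa > 1e-300:
        q1 = -(a[free] @ r[free]) / aa
    else:
        q1 = 0.0
    mu = r + q1 * a
    mu[free] = 0.0
    return q1, mu


def qp_subproblem(state: SQPState, sp: SplitProblem, hess_boost: float = 0.0):
    """Solve the convexified QP subproblem at the current iterate.

    Returns ``(p_hat, q_hat)`` where ``q_hat = [q1, mu...]`` stacks the
    equality multiplier first and the sign-constraint multipliers after it.
    """
    gamma = state.gamma
    g = sp.grad_f(gamma)
    a = sp.grad_g1(gamma)
    g1 = sp.g1(gamma)
    W = _convexified_hessian(sp, state.alpha[0], hess_boost)
    p, ok = _solve_qp(W, g, a, g1, gamma)
    if not ok:
        warnings.warn("QP subproblem unsolved even in elastic mode", stacklevel=2)
    q1, mu = _recover_multipliers(W, g, a, p, gamma)
    return p, np.concatenate([[q1], mu])


def merit_line_search(state: SQPState, sp: SplitProblem, p, q_hat, mu_pen):
    """Armijo backtracking on the exact-penalty merit phi = f + mu_pen |g1|.

    Returns the accepted step s in (0, 1], or None if no step above the
    minimum produces sufficient decrease.
    """
    gamma = state.gamma
    if np.abs(p).max() <= 1e-13 * (1.0 + np.abs(gamma).max()):
        return None  # zero direction cannot make progress
    D = sp.grad_f(gamma) @ p - mu_pen * abs(sp.g1(gamma))
    if D >= 0:
        return None  # not a descent direction for the merit function
    phi0 = sp.merit(gamma, mu_pen)
    s = 1.0
    while s >= _S_MIN:
        trial = sp.merit(np.maximum(gamma + s * p, 0.0), mu_pen)
        if trial <= phi0 + _ARMIJO * s * D and trial < phi0:
            return s
        s *= 0.5
    return None


def _kkt_residuals(sp, gamma, q1, mu):
    grad = sp.grad_f(gamma)
    a = sp.grad_g1(gamma)
    mu_pos = np.maximum(mu, 0.0)
    stat = np.abs(grad + q1 * a - mu_pos).max()
    comp = np.abs(mu_pos * gamma).max()
    feas = abs(sp.g1(gamma))
    scale = 1.0 + np.abs(grad).max()
    return stat, comp, feas, scale


def _solve_single(sp, gamma0, alpha0, max_iter, tol, feas_tol):
    state = SQPState(gamma=gamma0.copy(), alpha=alpha0.copy())
    mu_pen = 1.0
    hess_boost = 0.0
    converged = False
    for it in range(max_iter):
        state.n_iter = it + 1
        p, q_hat = qp_subproblem(state, sp, hess_boost)
        q1, mu = q_hat[0], q_hat[1:]
        stat, comp, feas, scale = _kkt_residuals(sp, state.gamma, q1, mu)
        state.kkt_residual = max(stat / scale, comp / scale, feas)
        if stat <= tol * scale and comp <= tol * scale and feas <= feas_tol:
            state.alpha = q_hat
            converged = True
            break
        mu_pen = max(mu_pen, abs(q1) + 1e-2)
        s = merit_line_search(state, sp, p, q_hat, mu_pen)
        if s is None:
            hess_boost = max(1e-6, hess_boost * 10.0)
            if hess_boost > 1e8:
                break
            continue
        state.gamma = np.maximum(state.gamma + s * p, 0.0)
        state.alpha = state.alpha + s * (q_hat - state.alpha)
        state.merit_value = sp.merit(state.gamma, mu_pen)
        state.merit_history.append(state.merit_value)
        state.step_history.append(s)
    return state, converged


def solve(
    sp: SplitProblem,
    max_iter: int = 500,
    tol: float = 1e-6,
    feas_tol: float = 1e-8,
    multi_start: int = 0,
    seed=None,
    return_state: bool = False,
):
    """Run the SQP from u = 1, v = 0, alpha = 1 and recover w = u - v.

    With ``multi_start = k > 0``, k additional seeded non-negative
    perturbations of the initial point are tried and the best KKT point
    (feasible, lowest objective) is kept; the split program is non-convex and
    only local convergence is guaranteed.
    """
    if max_iter < 1 or tol <= 0 or feas_tol <= 0:
        raise ValueError("invalid solver settings")
    d = sp.d
    if np.abs(sp.B2).max() == 0.0:
        raise ValueError("B is identically zero: the unit-variance constraint "
                         "is infeasible")
    starts = [np.concatenate([np.ones(d), np.zeros(d)])]
    if multi_start > 0:
        rng = np.random.default_rng(seed)
        for _ in range(multi_start):
            starts.append(rng.uniform(0.0, 1.5, size=2 * d))
    alpha0 = np.ones(sp.e)

    best = None
    for gamma0 in starts:
        state, conv = _solve_single(sp, gamma0, alpha0, max_iter, tol, feas_tol)
        obj = sp.f(state.gamma)
        key = (not conv, obj)  # converged first, then lowest objective
        if best is None or key < best[0]:
            best = (key, state, conv)
    _, state, converged = best

    # remove common mass min(u_i, v_i): w is unchanged, the quadratic forms
    # depend on gamma only through w, and the L1 linear term cannot increase
    common = np.minimum(state.u, state.v)
    gamma = state.gamma.copy()
    gamma[:d] -= common
    gamma[d:] -= common
    state.gamma = gamma

    w = state.u - state.v
    i = int(np.argmax(np.abs(w)))
    if w[i] < 0:  # canonical sign: largest-|w_i| entry positive
        w = -w
        state.gamma = np.concatenate([state.gamma[d:], state.gamma[:d]])
    w[np.abs(w) < _ZERO_W] = 0.0

    # objective/constraint in original w coordinates (A, B are the top-left
    # blocks of the split forms)
    A = sp.A2[:d, :d]
    B = sp.B2[:d, :d]
    model = TraitModel(
        w=w,
        lam=sp.lam,
        objective_value=float(w @ A @ w + (sp.lam / d) * np.abs(w).sum()),
        constraint_residual=float(abs(w @ B @ w - 1.0)),
        converged=converged,
        n_iter=state.n_iter,
        kkt_residual=state.kkt_residual,
        provenance={"multi_start": multi_start, "seed": seed,
                    "max_iter": max_iter, "tol": tol, "feas_tol": feas_tol},
    )
    if return_state:
        return model, state
    return model


def score_subjects(model: TraitModel, X_new) -> np.ndarray:
    """Trait values y = X_new w, applying the training normalization first.

    ``X_new`` may be a raw array (the stored min-max maps are applied) or a
    :class:`PhenotypeFeatureMatrix`; an already-normalized feature matrix is
    used as-is after its feature names are checked against the model.
    """
    if isinstance(X_new, PhenotypeFeatureMatrix):
        if model.feature_names is not None:
            missing = [f for f in model.feature_names
                       if f not in X_new.feature_names]
            extra = [f for f in X_new.feature_names
                     if f not in model.feature_names]
            if missing or extra or list(X_new.feature_names) != list(
                    model.feature_names):
                raise ValueError(
                    f"feature mismatch: missing={missing}, extra={extra}, "
                    f"order={list(X_new.feature_names)}"
                )
        Xm = X_new.X if X_new.normalized else _apply_maps(model, X_new.X)
    else:
        Xm = _apply_maps(model, np.asarray(X_new, dtype=float))
    if Xm.shape[1] != model.w.shape[0]:
        raise ValueError(
            f"expected {model.w.shape[0]} features, got {Xm.shape[1]}"
        )
    return Xm @ model.w


def _apply_maps(model, X):
    if model.data_min is None:
        return X
    return (X - model.data_min) / (model.data_max - model.data_min)
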