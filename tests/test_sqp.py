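import numpy as np
import pytest
from scipy.linalg import eigh
from scipy.optimize import LinearConstraint, minimize

from heritcomp.objective import PhenotypeFeatureMatrix, normalize_features
from heritcomp.sqp import (
    SQPState,
    merit_line_search,
    qp_subproblem,
    score_subjects,
    solve,
    split_variables,
)
from heritcomp.sqp import _solve_qp

from conftest import random_spd_pair


class TestSplitVariables:
    def test_block_structure_d1(self):
        sp = split_variables(np.array([[3.0]]), np.array([[1.0]]), 0.5)
        assert np.allclose(sp.A2, [[3.0, -3.0], [-3.0, 3.0]])
        assert np.allclose(sp.B2, [[1.0, -1.0], [-1.0, 1.0]])
        assert np.allclose(sp.lin, 0.5)
        assert sp.e == 3

    def test_quadratic_form_depends_only_on_difference(self):
        rng = np.random.default_rng(0)
        A, B = random_spd_pair(rng, 3)
        sp = split_variables(A, B, 0.1)
        for _ in range(20):
            gamma = rng.uniform(0, 2, size=6)
            w = gamma[:3] - gamma[3:]
            assert gamma @ sp.A2 @ gamma == pytest.approx(w @ A @ w, abs=1e-10)
            assert gamma @ sp.B2 @ gamma == pytest.approx(w @ B @ w, abs=1e-10)

    def test_pure_u_reduces_to_original_form(self):
        rng = np.random.default_rng(1)
        A, B = random_spd_pair(rng, 4)
        sp = split_variables(A, B, 0.0)
        u = rng.uniform(0, 1, 4)
        gamma = np.concatenate([u, np.zeros(4)])
        assert gamma @ sp.A2 @ gamma == pytest.approx(u @ A @ u, abs=1e-12)

    def test_negative_lambda_errors(self):
        with pytest.raises(ValueError):
            split_variables(np.eye(2), np.eye(2), -0.1)


class TestQpSubproblem:
    def test_zero_direction_at_kkt_point(self):
        rng = np.random.default_rng(2)
        A, B = random_spd_pair(rng, 3)
        sp = split_variables(A, B, 0.01)
        model, state = solve(sp, return_state=True)
        assert model.converged
        p, _ = qp_subproblem(state, sp)
        assert np.abs(p).max() < 1e-5

    def test_matches_generic_qp_oracle(self):
        rng = np.random.default_rng(3)
        A, B = random_spd_pair(rng, 2)
        sp = split_variables(A, B, 0.05)
        gamma = np.array([1.0, 0.5, 0.2, 0.8])
        state = SQPState(gamma=gamma, alpha=np.ones(sp.e))
        p, _ = qp_subproblem(state, sp)
        # oracle: scipy trust-constr on the same convexified QP
        from heritcomp.sqp import _convexified_hessian

        W = _convexified_hessian(sp, 1.0)
        g = sp.grad_f(gamma)
        a = sp.grad_g1(gamma)
        g1 = sp.g1(gamma)
        res = minimize(
            lambda x: 0.5 * x @ W @ x + g @ x,
            np.zeros(4),
            jac=lambda x: W @ x + g,
            hess=lambda x: W,
            method="trust-constr",
            bounds=[(-gi, None) for gi in gamma],
            constraints=[LinearConstraint(a, -g1, -g1)],
            options={"gtol": 1e-12, "xtol": 1e-14},
        )
        # tolerance limited by the interior-point oracle's barrier precision
        assert np.abs(p - res.x).max() < 1e-5

    def test_projection_closed_form(self):
        # with W = I, g1 = 0 and interior bounds the step is the projection
        # of -grad onto the null space of the linearized constraint
        rng = np.random.default_rng(4)
        m = 6
        g = rng.standard_normal(m)
        a = rng.standard_normal(m)
        gamma = np.full(m, 100.0)  # bounds far away
        p, ok = _solve_qp(np.eye(m), g, a, 0.0, gamma)
        assert ok
        proj = -(g - a * (a @ g) / (a @ a))
        assert np.abs(p - proj).max() < 1e-8


class TestMeritLineSearch:
    def test_full_step_accepted_when_merit_decreases(self):
        A = np.array([[1.0]])
        B = np.array([[1.0]])
        sp = split_variables(A, B, 0.0)
        gamma = np.array([2.0, 0.0])  # w = 2, f = 4, g1 = 3
        state = SQPState(gamma=gamma, alpha=np.ones(3))
        p = np.array([-1.0, 0.0])  # move to w = 1 (feasible, f = 1)
        s = merit_line_search(state, sp, p, np.zeros(3), mu_pen=1.0)
        assert s == 1.0

    def test_armijo_inequality_on_scalar_quadratic(self):
        # phi(gamma + s p) is known in closed form for this 1-d problem
        A = np.array([[2.0]])
        B = np.array([[1.0]])
        sp = split_variables(A, B, 0.0)
        gamma = np.array([3.0, 0.0])
        state = SQPState(gamma=gamma, alpha=np.ones(3))
        p = np.array([-1.0, 0.0])
        mu_pen = 1.0
        s = merit_line_search(state, sp, p, np.zeros(3), mu_pen)
        assert s is not None

        def phi(w):
            return 2.0 * w**2 + mu_pen * abs(w**2 - 1.0)

        D = sp.grad_f(gamma) @ p - mu_pen * abs(sp.g1(gamma))
        assert phi(3.0 - s) <= phi(3.0) + 1e-4 * s * D

    def test_merit_history_non_increasing(self):
        rng = np.random.default_rng(5)
        A, B = random_spd_pair(rng, 4)
        _, state = solve(split_variables(A, B, 0.3), return_state=True)
        hist = state.merit_history
        assert len(hist) >= 1
        assert all(b <= a + 1e-9 for a, b in zip(hist, hist[1:]))


class TestSolve:
    def test_unpenalized_matches_generalized_eigenvector_oracle(self):
        rng = np.random.default_rng(6)
        failures = 0
        for _ in range(20):
            d = int(rng.integers(2, 7))
            A, B = random_spd_pair(rng, d)
            model = solve(split_variables(A, B, 0.0))
            vals, vecs = eigh(A, B)
            gap = model.objective_value - vals[0]
            v = vecs[:, 0] / np.sqrt(vecs[:, 0] @ B @ vecs[:, 0])
            aligned = min(np.abs(model.w - v).max(), np.abs(model.w + v).max())
            if not (model.converged and gap <= 1e-6 and aligned < 1e-3):
                failures += 1
        assert failures == 0

    def test_diagonal_large_penalty_concentrates_on_best_axis(self):
        A = np.diag([3.0, 1.0, 2.0])
        B = np.diag([1.0, 1.0, 4.0])
        lam = 50.0
        model = solve(split_variables(A, B, lam))
        # oracle: enumerate axis-feasible points w = +- e_i / sqrt(B_ii)
        objs = [A[i, i] / B[i, i] + (lam / 3) / np.sqrt(B[i, i])
                for i in range(3)]
        best_axis = int(np.argmin(objs))
        support = np.flatnonzero(model.w)
        assert list(support) == [best_axis]
        assert model.objective_value == pytest.approx(objs[best_axis],
                                                      rel=1e-6)

    def test_constraint_and_complementarity_at_convergence(self):
        rng = np.random.default_rng(7)
        for lam in (0.0, 0.05, 0.5):
            A, B = random_spd_pair(rng, 5)
            model, state = solve(split_variables(A, B, lam),
                                 return_state=True)
            assert model.converged
            assert model.constraint_residual <= 1e-6
            assert np.minimum(state.u, state.v).max() <= 1e-8
            l1_gamma = state.gamma.sum()
            assert l1_gamma == pytest.approx(np.abs(model.w).sum(), abs=1e-8)

    def test_l1_norm_monotone_in_penalty(self):
        rng = np.random.default_rng(8)
        A, B = random_spd_pair(rng, 5)
        prev = np.inf
        for lam in (0.0, 0.01, 0.1, 0.5, 2.0):
            model = solve(split_variables(A, B, lam))
            l1 = np.abs(model.w).sum()
            assert l1 <= prev + 1e-6
            prev = l1

    def test_appending_feature_cannot_raise_unpenalized_minimum(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            d = 4
            A, B = random_spd_pair(rng, d + 1)
            sub = solve(split_variables(A[:d, :d], B[:d, :d], 0.0))
            full_min = eigh(A, B, eigvals_only=True)[0]
            assert full_min <= sub.objective_value + 1e-6

    def test_sign_canonicalization_and_exact_zeros(self):
        A = np.diag([5.0, 1.0])
        B = np.eye(2)
        model = solve(split_variables(A, B, 10.0))
        assert model.w[np.argmax(np.abs(model.w))] > 0
        assert model.w[0] == 0.0  # hard zero, not just small

    def test_zero_B_errors(self):
        with pytest.raises(ValueError, match="infeasible|zero"):
            solve(split_variables(np.eye(2), np.zeros((2, 2)), 0.0))

    def test_invalid_settings_error(self):
        sp = split_variables(np.eye(2), np.eye(2), 0.0)
        with pytest.raises(ValueError):
            solve(sp, max_iter=0)
        with pytest.raises(ValueError):
            solve(sp, tol=-1.0)

    def test_multi_start_keeps_best_point(self):
        rng = np.random.default_rng(10)
        A, B = random_spd_pair(rng, 4)
        single = solve(split_variables(A, B, 0.0))
        multi = solve(split_variables(A, B, 0.0), multi_start=3, seed=0)
        assert multi.objective_value <= single.objective_value + 1e-9


class TestScoreSubjects:
    def _model(self, w, **kw):
        from heritcomp.sqp import TraitModel

        return TraitModel(w=np.asarray(w, float), lam=0.0, objective_value=0.0,
                          constraint_residual=0.0, converged=True, **kw)

    def test_unit_weight_selects_feature(self):
        X = np.random.default_rng(0).standard_normal((5, 3))
        model = self._model([1.0, 0.0, 0.0])
        assert np.array_equal(score_subjects(model, X), X[:, 0])

    def test_training_matrix_reproduces_training_scores(self):
        rng = np.random.default_rng(1)
        raw = rng.uniform(0, 10, size=(6, 3))
        pfm = normalize_features(raw, ["a", "b", "c"])
        model = self._model([0.5, -1.0, 2.0], feature_names=["a", "b", "c"],
                            data_min=pfm.data_min, data_max=pfm.data_max)
        direct = pfm.X @ model.w
        assert np.array_equal(score_subjects(model, pfm), direct)
        # raw values run through the stored affine map give the same scores
        assert np.allclose(score_subjects(model, raw), direct)

    def test_feature_mismatch_error_lists_names(self):
        model = self._model([1.0, 2.0], feature_names=["a", "b"])
        bad = PhenotypeFeatureMatrix(X=np.zeros((2, 2)),
                                     feature_names=["a", "c"])
        with pytest.raises(ValueError, match="c"):
            score_subjects(model, bad)
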