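"""Objective, gradient, proximal operator and the APG solver."""

import numpy as np
import pytest

import longfs
from longfs import Hyperparams, prox_nonsmooth, tv1d_denoise
from longfs.solver import CohortTable, _nonsmooth_value
from conftest import make_cohort
from helpers_oracles import objective_loops, prox_oracle, subgradient_descent


def hp0(**kw):
    return Hyperparams(**{"beta": 0.0, "lam": 0.0, "mu": 0.0, **kw})


class TestCohortTable:
    def test_missing_cell_rejected(self, rng):
        cells = {(0, 0): rng.normal(size=(4, 2)), (0, 1): rng.normal(size=(4, 2)),
                 (1, 0): rng.normal(size=(4, 2))}
        y = np.array([1, 1, -1, -1])
        with pytest.raises(ValueError, match="missing"):
            CohortTable(cells, y)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="both classes"):
            CohortTable({(0, 0): rng.normal(size=(3, 2))}, np.ones(3))

    def test_restrict_reindexes(self, tiny_cohort):
        table, _ = tiny_cohort
        sub = table.restrict(timepoints=[1])
        assert sub.n_timepoints == 1
        assert np.array_equal(sub.cell(0, 0), table.cell(0, 1))


class TestObjective:
    def test_zero_weights_value(self, tiny_cohort, zero_laps):
        table, _ = tiny_cohort
        y = np.asarray(table.labels, dtype=float)
        W = np.zeros((1, 10, 2))
        val = longfs.objective(table, zero_laps(table), W, Hyperparams())
        assert val == pytest.approx(0.5 * 1 * 2 * float(y @ y))

    def test_identical_columns_kill_fused_term(self, rng):
        W = np.repeat(rng.normal(size=(2, 5, 1)), 3, axis=2)
        assert _nonsmooth_value(W, 0.0, 7.5) == pytest.approx(0.0)

    def test_matches_loop_oracle(self, knn_laps):
        table, _ = make_cohort(n=4, d=3, T=2, M=1, seed=7)
        laps = knn_laps(table, k=2)
        rng = np.random.default_rng(3)
        W = rng.normal(size=(1, 3, 2))
        hp = Hyperparams(beta=0.3, lam=0.2, mu=0.4)
        expected = objective_loops(table, laps, W, 0.3, 0.2, 0.4)
        assert longfs.objective(table, laps, W, hp) == pytest.approx(expected, rel=1e-10)


class TestSmoothGradient:
    def test_zero_at_least_squares_minimizer(self, zero_laps):
        table, _ = make_cohort(n=20, d=5, T=1, M=1, seed=1)
        X = table.cell(0, 0)
        y = np.asarray(table.labels, dtype=float)
        w = np.linalg.lstsq(X, y, rcond=None)[0]
        g = longfs.smooth_gradient(table, zero_laps(table), w.reshape(1, 5, 1), hp0())
        assert np.abs(g).max() < 1e-8

    def test_matches_finite_differences(self, knn_laps):
        table, _ = make_cohort(n=8, d=3, T=2, M=1, seed=2)
        laps = knn_laps(table, k=3)
        hp = Hyperparams(beta=0.0, lam=0.3, mu=0.0)
        rng = np.random.default_rng(0)
        W = rng.normal(size=(1, 3, 2))
        G = longfs.smooth_gradient(table, laps, W, hp)

        def h(Wx):
            return longfs.objective(table, laps, Wx, hp)  # beta=mu=0 -> smooth only

        eps = 1e-6
        for idx in np.ndindex(W.shape):
            Wp, Wm = W.copy(), W.copy()
            Wp[idx] += eps
            Wm[idx] -= eps
            fd = (h(Wp) - h(Wm)) / (2 * eps)
            assert G[idx] == pytest.approx(fd, abs=1e-5)

    def test_orthonormal_design_closed_form(self, zero_laps):
        rng = np.random.default_rng(4)
        Q, _ = np.linalg.qr(rng.normal(size=(12, 4)))
        y = np.where(rng.random(12) < 0.5, 1, -1)
        y[:2] = [1, -1]
        table = CohortTable({(0, 0): Q}, y)
        w = rng.normal(size=(1, 4, 1))
        g = longfs.smooth_gradient(table, zero_laps(table), w, hp0())
        expected = w[0, :, 0] - Q.T @ y
        assert np.allclose(g[0, :, 0], expected, atol=1e-10)


class TestTV1D:
    def test_no_penalty_identity(self, rng):
        y = rng.normal(size=6)
        assert np.array_equal(tv1d_denoise(y, 0.0), y)

    def test_large_penalty_gives_mean(self, rng):
        y = rng.normal(size=5)
        assert np.allclose(tv1d_denoise(y, 100.0), np.full(5, y.mean()), atol=1e-10)

    def test_kkt_of_solution(self, rng):
        """Dual certificate: cumulative residual stays inside [-lam, lam]
        and hits the boundary consistently with the jump signs."""
        for _ in range(50):
            n = int(rng.integers(2, 9))
            y = rng.normal(size=n) * 3
            lam = float(rng.uniform(0.05, 2))
            x = tv1d_denoise(y, lam)
            z = np.cumsum(y - x)[:-1]  # dual variables
            assert np.abs(z).max() <= lam + 1e-9
            jumps = np.diff(x)
            for i, j in enumerate(jumps):
                if j > 1e-10:
                    assert z[i] == pytest.approx(-lam, abs=1e-9)
                elif j < -1e-10:
                    assert z[i] == pytest.approx(lam, abs=1e-9)
            assert abs(np.sum(y - x)) <= 1e-9  # total mass preserved


class TestProx:
    def test_zero_penalty_identity(self, rng):
        V = rng.normal(size=(2, 3, 4))
        assert np.allclose(prox_nonsmooth(V, 0.7, hp0()), V)

    def test_full_shrinkage_to_zero(self, rng):
        V = rng.normal(size=(1, 4, 3))
        out = prox_nonsmooth(V, 1.0, Hyperparams(beta=1e6, lam=0.0, mu=0.1))
        assert np.array_equal(out, np.zeros_like(V))

    def test_nonpositive_step_rejected(self, rng):
        with pytest.raises(ValueError, match="step"):
            prox_nonsmooth(rng.normal(size=(1, 2, 2)), 0.0, hp0())

    def test_small_instance_matches_convex_oracle(self):
        rng = np.random.default_rng(11)
        V = rng.normal(size=(1, 2, 3)) * 2
        step, beta, mu = 0.8, 0.6, 0.4
        got = prox_nonsmooth(V, step, Hyperparams(beta=beta, lam=0.0, mu=mu))
        want = prox_oracle(V, step, beta, mu)
        assert np.abs(got - want).max() < 1e-4

    def test_agrees_with_oracle_many_random(self):
        rng = np.random.default_rng(99)
        worst = 0.0
        for _ in range(50):
            d, T = int(rng.integers(1, 5)), int(rng.integers(1, 5))
            V = rng.normal(size=(1, d, T)) * rng.uniform(0.5, 3)
            step = float(rng.uniform(0.1, 2))
            beta = float(rng.uniform(0.05, 1))
            mu = float(rng.uniform(0.05, 1))
            got = prox_nonsmooth(V, step, Hyperparams(beta=beta, lam=0.0, mu=mu))
            want = prox_oracle(V, step, beta, mu)
            worst = max(worst, float(np.abs(got - want).max()))
        assert worst < 1e-4

    def test_firmly_nonexpansive(self):
        rng = np.random.default_rng(5)
        hp = Hyperparams(beta=0.5, lam=0.0, mu=0.7)
        for _ in range(100):
            u = rng.normal(size=(2, 3, 4))
            v = rng.normal(size=(2, 3, 4))
            pu = prox_nonsmooth(u, 1.0, hp)
            pv = prox_nonsmooth(v, 1.0, hp)
            assert np.linalg.norm(pu - pv) <= np.linalg.norm(u - v) + 1e-12


class TestFit:
    def test_reduces_to_least_squares(self):
        """beta=lam=mu=0 with M=T=1 and overdetermined X is plain OLS."""
        table, _ = make_cohort(n=30, d=5, T=1, M=1, seed=6)
        W, state = longfs.fit(table, hp0(tol=1e-15, max_iter=20000))
        X = table.cell(0, 0)
        y = np.asarray(table.labels, dtype=float)
        w_star = np.linalg.pinv(X) @ y
        assert np.abs(W[0, :, 0] - w_star).max() < 1e-6
        assert state.converged

    def test_beats_subgradient_oracle(self, knn_laps):
        table, _ = make_cohort(n=20, d=10, T=2, M=1, seed=8)
        laps = knn_laps(table, k=3)
        hp = Hyperparams(beta=0.5, lam=0.1, mu=0.3, k=3, tol=1e-10, max_iter=3000)
        W, state = longfs.fit(table, hp, laps=laps)
        oracle = subgradient_descent(table, laps, 0.5, 0.1, 0.3, n_steps=20000)
        assert state.objective_trace[-1] <= oracle + 1e-4

    @pytest.mark.parametrize("reduction", ["fused_group", "l21_only"])
    def test_reductions_beat_subgradient_oracle(self, zero_laps, reduction):
        """lam=0, M=1 is fused sparse group selection; mu=lam=0 is plain
        l2,1 multi-task selection — both must still reach the optimum."""
        table, _ = make_cohort(n=16, d=6, T=3, M=1, seed=9)
        laps = zero_laps(table)
        mu = 0.4 if reduction == "fused_group" else 0.0
        hp = Hyperparams(beta=0.8, lam=0.0, mu=mu, tol=1e-10, max_iter=3000)
        W, state = longfs.fit(table, hp, laps=laps)
        oracle = subgradient_descent(table, laps, 0.8, 0.0, mu, n_steps=20000)
        assert state.objective_trace[-1] <= oracle + 1e-4

    def test_huge_beta_zeroes_everything(self, tiny_cohort):
        table, _ = tiny_cohort
        W, _ = longfs.fit(table, Hyperparams(beta=1e6, lam=0.0, mu=0.0))
        assert np.array_equal(W, np.zeros_like(W))

    def test_trace_monotone_nonincreasing(self):
        for seed in range(3):
            table, _ = make_cohort(n=14, d=8, T=2, M=2, seed=seed)
            _, state = longfs.fit(table, Hyperparams(beta=0.3, lam=0.05, mu=0.2, k=3))
            tr = np.array(state.objective_trace)
            assert np.all(np.diff(tr) <= 1e-10)

    def test_nonconvergence_flag_not_exception(self, tiny_cohort):
        table, _ = tiny_cohort
        with pytest.warns(RuntimeWarning, match="max_iter"):
            _, state = longfs.fit(table, Hyperparams(beta=0.1, lam=0.0, mu=0.1,
                                                     max_iter=2, tol=1e-16))
        assert not state.converged

    def test_large_mu_tightens_temporal_differences(self):
        table, _ = make_cohort(n=20, d=8, T=3, M=1, seed=13)
        def fused_sum(W):
            return float(np.abs(np.diff(W, axis=2)).sum())
        W_hi, _ = longfs.fit(table, Hyperparams(beta=0.1, lam=0.01, mu=5.0, k=3))
        W_lo, _ = longfs.fit(table, Hyperparams(beta=0.1, lam=0.01, mu=0.0001, k=3))
        assert fused_sum(W_hi) <= fused_sum(W_lo)


class TestSelectFeatures:
    def test_zero_weights_empty(self):
        sel = longfs.select_features(np.zeros((2, 4, 3)))
        assert all(len(s) == 0 for s in sel.per_modality)

    def test_single_nonzero_row(self):
        W = np.zeros((1, 5, 3))
        W[0, 2, 0] = 0.5
        W[0, 2, 2] = -0.3
        sel = longfs.select_features(W)
        assert sel.per_modality[0] == (2,)
        assert set(sel.per_timepoint[0]) == {(2, 0), (2, 2)}

    def test_threshold_filters(self):
        W = np.full((1, 2, 2), 1e-10)
        assert longfs.select_features(W, threshold=1e-8).per_modality[0] == ()
        assert longfs.select_features(W, threshold=0.0).per_modality[0] == (0, 1)
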