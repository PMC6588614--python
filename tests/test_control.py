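"""H2 cost machinery, closed-form centralized oracle, ADMM and polishing."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest
import scipy.optimize

from netsparse.control import (
    AdmmOptions,
    LaplacianSystem,
    centralized_gain,
    controllability_gramian,
    h2_cost,
    h2_gradient,
    laplacian,
    observability_gramian,
    polish_gain,
    solve_gamma_path,
    sparse_gain_admm,
    total_cost,
)
from netsparse.exceptions import ClosedLoopUnstableError, InfeasiblePatternError
from netsparse.netgen import init_random_graph


def scalar_system():
    return LaplacianSystem(L=np.zeros((1, 1)))


def random_feasible_gain(system, rng, scale=0.2):
    """Centralized optimum plus a small random perturbation (stays Hurwitz)."""
    f_star, _ = centralized_gain(system)
    return f_star + scale * rng.standard_normal(f_star.shape) / system.n


class TestLaplacianSystem:
    def test_k2_matrix(self):
        system = laplacian(nx.complete_graph(2))
        assert np.array_equal(system.L, [[1.0, -1.0], [-1.0, 1.0]])
        assert np.array_equal(system.B1, np.eye(2))

    def test_rows_sum_to_zero(self, rng):
        system = laplacian(init_random_graph(15, 30, rng))
        assert np.allclose(system.L.sum(axis=1), 0.0)

    def test_zero_eigenvalue_counts_components(self, rng):
        g = nx.disjoint_union(nx.cycle_graph(5), nx.path_graph(4))
        lam = np.linalg.eigvalsh(laplacian(g).L)
        assert np.sum(np.abs(lam) < 1e-9) == 2


class TestGramians:
    def test_scalar_observability(self):
        p = observability_gramian(scalar_system(), np.array([[1.0]]))
        assert p[0, 0] == pytest.approx(1.0)  # 2P = 1 + 1

    def test_marginally_stable_rejected(self):
        with pytest.raises(ClosedLoopUnstableError):
            observability_gramian(scalar_system(), np.array([[0.0]]))

    def test_scalar_controllability(self):
        w = controllability_gramian(scalar_system(), np.array([[2.0]]))
        assert w[0, 0] == pytest.approx(0.25)

    def test_gramians_psd_and_trace_identity(self, rng):
        g = init_random_graph(8, 14, rng)
        system = laplacian(g)
        f = random_feasible_gain(system, rng)
        p = observability_gramian(system, f)
        w = controllability_gramian(system, f)
        assert np.allclose(p, p.T) and np.linalg.eigvalsh(p).min() >= -1e-10
        assert np.allclose(w, w.T) and np.linalg.eigvalsh(w).min() >= -1e-10
        lhs = np.trace(system.B1.T @ p @ system.B1)
        rhs = np.trace((np.eye(8) + f.T @ f) @ w)
        assert lhs == pytest.approx(rhs, rel=1e-6)

    def test_lyapunov_residual_small(self, rng):
        system = laplacian(init_random_graph(10, 20, rng))
        f = random_feasible_gain(system, rng)
        p = observability_gramian(system, f)
        acl = -(system.L + f)
        q = np.eye(10) + f.T @ f
        residual = acl.T @ p + p @ acl + q
        assert np.linalg.norm(residual) <= 1e-8 * np.linalg.norm(q)


class TestH2Cost:
    @pytest.mark.parametrize("f,expected", [(2.0, 1.25), (1.0, 1.0)])
    def test_scalar_closed_form(self, f, expected):
        # J = (1 + f^2) / (2 f)
        assert h2_cost(scalar_system(), np.array([[f]])) == pytest.approx(expected)

    def test_k2_centralized(self):
        system = laplacian(nx.complete_graph(2))
        f_star, _ = centralized_gain(system)
        assert h2_cost(system, f_star) == pytest.approx(math.sqrt(5) - 1, rel=1e-10)


class TestH2Gradient:
    def test_scalar_formula(self):
        f = 2.0
        g = h2_gradient(scalar_system(), np.array([[f]]))
        assert g[0, 0] == pytest.approx((f**2 - 1) / (2 * f**2))

    def test_zero_at_centralized_optimum(self, rng):
        system = laplacian(init_random_graph(6, 10, rng))
        f_star, _ = centralized_gain(system)
        assert np.linalg.norm(h2_gradient(system, f_star)) <= 1e-6

    def test_matches_finite_differences(self, rng):
        system = laplacian(init_random_graph(5, 8, rng))
        f = random_feasible_gain(system, rng)
        grad = h2_gradient(system, f)
        step = 1e-6
        for i, j in itertools.product(range(5), repeat=2):
            fp, fm = f.copy(), f.copy()
            fp[i, j] += step
            fm[i, j] -= step
            fd = (h2_cost(system, fp) - h2_cost(system, fm)) / (2 * step)
            assert grad[i, j] == pytest.approx(fd, rel=1e-4, abs=1e-7)


class TestCentralizedGain:
    def test_empty_graph(self):
        system = LaplacianSystem(L=np.zeros((5, 5)))
        f, j = centralized_gain(system)
        assert np.allclose(f, np.eye(5))
        assert j == pytest.approx(5.0)

    @pytest.mark.parametrize(
        "graph,expected",
        [
            (nx.complete_graph(2), 1 + (math.sqrt(5) - 2)),
            (nx.complete_graph(3), 1 + 2 * (math.sqrt(10) - 3)),
        ],
    )
    def test_small_complete_graphs(self, graph, expected):
        _, j = centralized_gain(laplacian(graph))
        assert j == pytest.approx(expected, rel=1e-12)

    def test_matches_lyapunov_cost_and_is_stationary(self, rng):
        system = laplacian(init_random_graph(12, 25, rng))
        f_star, j_star = centralized_gain(system)
        assert h2_cost(system, f_star) == pytest.approx(j_star, rel=1e-9)


class TestSparseGainAdmm:
    def test_gamma_zero_recovers_centralized(self, rng):
        system = laplacian(init_random_graph(10, 25, rng))
        _, j_star = centralized_gain(system)
        sol = sparse_gain_admm(system, 0.0)
        assert sol.costs.J == pytest.approx(j_star, rel=1e-5)
        assert sol.costs.card == 100  # dense

    def test_scalar_small_gamma(self):
        sol = sparse_gain_admm(scalar_system(), 0.01)
        assert sol.gain[0, 0] == pytest.approx(1.0, rel=1e-4)
        assert sol.costs.card == 1
        assert sol.costs.total == pytest.approx(1.01, rel=1e-4)

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            sparse_gain_admm(scalar_system(), -1.0)

    def test_k2_sweep_monotone_and_near_bruteforce(self):
        system = laplacian(nx.complete_graph(2))
        gammas = [1e-4, 1e-2, 1e-1]
        sols = solve_gamma_path(system, gammas)
        cards = [s.costs.card for s in sols]
        js = [s.costs.J for s in sols]
        assert cards == sorted(cards, reverse=True)
        assert js == sorted(js)
        # oracle: minimize J + gamma*card over all 16 patterns, polishing
        # each; the ADMM is a local method, so its total can never beat the
        # brute-force global optimum, and at the smallest gamma (where the
        # dense pattern is globally optimal) it must attain it
        for gamma, sol in zip(gammas, sols):
            best = math.inf
            for bits in itertools.product([0, 1], repeat=4):
                pattern = np.array(bits, dtype=bool).reshape(2, 2)
                if not pattern.any():
                    continue
                try:
                    _, j = polish_gain(system, pattern)
                except InfeasiblePatternError:
                    continue
                best = min(best, j + gamma * pattern.sum())
            assert sol.costs.total >= best * (1 - 1e-6)
            if gamma == gammas[0]:
                assert sol.costs.total == pytest.approx(best, rel=1e-4)

    def test_homotopy_monotone_on_small_graph(self, rng):
        system = laplacian(init_random_graph(8, 16, rng))
        sols = solve_gamma_path(system, list(np.logspace(-4, -1, 5)))
        cards = [s.costs.card for s in sols]
        js = [s.costs.J for s in sols]
        assert all(a >= b for a, b in zip(cards, cards[1:]))
        assert all(a <= b * (1 + 1e-9) for a, b in zip(js, js[1:]))

    def test_returned_gain_is_stabilizing(self, rng):
        system = laplacian(init_random_graph(12, 24, rng))
        sol = sparse_gain_admm(system, 1e-2)
        acl = -(system.L + sol.gain)
        assert np.linalg.eigvals(acl).real.max() < 0


class TestPolishGain:
    def test_full_pattern_is_centralized(self, rng):
        system = laplacian(init_random_graph(7, 12, rng))
        f_star, j_star = centralized_gain(system)
        f, j = polish_gain(system, np.ones((7, 7), dtype=bool))
        assert j == pytest.approx(j_star, rel=1e-6)

    def test_k2_diagonal_pattern_vs_nelder_mead(self):
        system = laplacian(nx.complete_graph(2))
        _, j = polish_gain(system, np.eye(2, dtype=bool))

        def objective(x):
            try:
                return h2_cost(system, np.diag(x))
            except ClosedLoopUnstableError:
                return 1e9

        res = scipy.optimize.minimize(
            objective, [1.0, 1.0], method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12},
        )
        assert j == pytest.approx(res.fun, rel=1e-4)

    def test_empty_pattern_infeasible(self):
        system = laplacian(nx.path_graph(3))
        with pytest.raises(InfeasiblePatternError):
            polish_gain(system, np.zeros((3, 3), dtype=bool))

    def test_gain_zero_off_pattern(self, rng):
        system = laplacian(init_random_graph(9, 18, rng))
        pattern = np.eye(9, dtype=bool)
        f, _ = polish_gain(system, pattern)
        assert np.all(f[~pattern] == 0.0)


class TestTotalCost:
    def test_gamma_zero(self, rng):
        system = laplacian(init_random_graph(6, 9, rng))
        f, _ = centralized_gain(system)
        cb = total_cost(system, f, 0.0)
        assert cb.total == cb.J

    def test_scalar_accounting(self):
        cb = total_cost(scalar_system(), np.array([[1.0]]), 0.01)
        assert cb.total == pytest.approx(1.01)
        assert cb.card == 1

    def test_sparse_never_beats_centralized_on_j(self, rng):
        system = laplacian(init_random_graph(10, 20, rng))
        _, j_star = centralized_gain(system)
        sol = sparse_gain_admm(system, 1e-1)
        assert sol.costs.J >= j_star - 1e-9
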