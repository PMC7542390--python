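"""Group-penalized neighborhood selection: design, solver, network assembly."""

import numpy as np
import pytest
from scipy.optimize import minimize

import zili
from zili.network import (
    FitConfig,
    build_design,
    fit_group_logistic_path,
    fit_zili,
    kkt_residuals,
    neighborhood_select,
)


def _mixture_states(rng, n, p, copy_prob=0.5):
    """i.i.d. 3-state taxa where taxon 1 copies taxon 0 with given probability
    (all conditional probabilities strictly positive)."""
    vals = rng.integers(0, 3, size=(n, p))
    vals[:, 1] = np.where(rng.random(n) < copy_prob, vals[:, 0], vals[:, 1])
    return zili.StateMatrix(values=vals, levels=[3] * p)


class TestBuildDesign:
    def test_shapes_and_groups(self):
        rng = np.random.default_rng(0)
        sm = zili.StateMatrix(values=rng.integers(0, 3, (40, 8)), levels=[3] * 8)
        y, X, group_taxa, slices = build_design(sm, 3)
        assert X.shape == (40, 14)  # 7 groups x (K-1)
        assert group_taxa == [0, 1, 2, 4, 5, 6, 7]
        assert all(sl.stop - sl.start == 2 for sl in slices)

    def test_columns_are_level_indicators(self):
        sm = zili.StateMatrix(values=[[0, 2], [1, 1], [0, 0]], levels=[2, 3])
        y, X, group_taxa, slices = build_design(sm, 0)
        np.testing.assert_array_equal(X, [[0, 1], [1, 0], [0, 0]])
        # per sample, a group's columns sum to I[Z_t != 0]
        np.testing.assert_array_equal(X.sum(axis=1), [1, 1, 0])

    def test_degenerate_taxa_excluded(self):
        sm = zili.StateMatrix(
            values=[[0, 1, 0], [1, 0, 0]], levels=[2, 2, 1]
        )
        y, X, group_taxa, slices = build_design(sm, 0)
        assert group_taxa == [1]
        with pytest.raises(ValueError):
            build_design(sm, 2)


class TestSolver:
    def test_lambda_max_gives_exact_null_model(self):
        rng = np.random.default_rng(1)
        sm = _mixture_states(rng, 120, 5)
        y, X, _, slices = build_design(sm, 0)
        path = fit_group_logistic_path(y, X, slices, FitConfig())
        first = path[0]
        assert first.df == 0
        assert all(not np.any(blk) for blk in first.blocks)
        freq = np.bincount(y, minlength=3) / len(y)
        np.testing.assert_allclose(
            first.intercepts, np.log(freq[1:] / freq[0]), atol=1e-6
        )

    def test_unpenalized_limit_matches_independent_optimizer(self):
        rng = np.random.default_rng(1)
        sm = _mixture_states(rng, 300, 3)
        y, X, _, slices = build_design(sm, 0)
        path = fit_group_logistic_path(
            y, X, slices,
            FitConfig(lambda_path=np.array([1e-7]), tol=1e-10, max_iter=20000),
        )
        pt = path[0]
        n = len(y)

        def nll(par):
            b, B = par[:2], par[2:].reshape(4, 2)
            eta = b + X @ B
            m = np.maximum(eta.max(axis=1, keepdims=True), 0.0)
            lse = (m + np.log(np.exp(-m) + np.exp(eta - m).sum(1, keepdims=True)))
            pick = np.where(y > 0, eta[np.arange(n), y - 1], 0.0)
            return lse.sum() - pick.sum()

        ref = minimize(nll, np.zeros(10), method="BFGS",
                       options={"gtol": 1e-12, "maxiter": 5000})
        assert np.abs(np.vstack(pt.blocks) - ref.x[2:].reshape(4, 2)).max() < 1e-4
        assert np.abs(pt.intercepts - ref.x[:2]).max() < 1e-4

    def test_kkt_conditions_along_path(self):
        rng = np.random.default_rng(7)
        sm = _mixture_states(rng, 80, 5)
        y, X, _, slices = build_design(sm, 0)
        path = fit_group_logistic_path(
            y, X, slices, FitConfig(n_lambda=10, tol=1e-8, max_iter=5000)
        )
        for pt in path:
            zero_excess, active_resid, intercept_grad = kkt_residuals(
                y, X, slices, pt
            )
            assert zero_excess <= 1e-4
            assert active_resid <= 1e-4
            assert intercept_grad <= 1e-4

    def test_objective_monotone_within_each_lambda(self):
        rng = np.random.default_rng(8)
        sm = _mixture_states(rng, 100, 4)
        y, X, _, slices = build_design(sm, 0)
        path = fit_group_logistic_path(
            y, X, slices, FitConfig(n_lambda=8), track_objective=True
        )
        for pt in path:
            trace = pt.objective_trace
            assert all(b <= a + 1e-8 for a, b in zip(trace, trace[1:]))

    def test_active_set_monotone_along_path(self):
        rng = np.random.default_rng(9)
        sm = _mixture_states(rng, 150, 6)
        y, X, _, slices = build_design(sm, 0)
        path = fit_group_logistic_path(y, X, slices, FitConfig(n_lambda=25))
        ngroups = [sum(bool(np.any(blk)) for blk in pt.blocks) for pt in path]
        # nonincreasing in lambda == nondecreasing along the descending path
        violations = sum(b < a for a, b in zip(ngroups, ngroups[1:]))
        assert violations <= 1  # rare coordinate-descent ties allowed

    def test_gamma_zero_is_bic_and_larger_gamma_is_sparser(self):
        rng = np.random.default_rng(10)
        sm = _mixture_states(rng, 150, 6, copy_prob=0.6)
        y, X, _, slices = build_design(sm, 0)
        path = fit_group_logistic_path(y, X, slices, FitConfig(ebic_gamma=0.0))
        n = len(y)
        for pt in path:
            assert pt.ebic == pytest.approx(-2 * pt.loglik + pt.df * np.log(n))
        path_half = fit_group_logistic_path(y, X, slices, FitConfig(ebic_gamma=0.5))
        df0 = path[int(np.argmin([p.ebic for p in path]))].df
        df5 = path_half[int(np.argmin([p.ebic for p in path_half]))].df
        assert df5 <= df0


class TestNeighborhoodSelect:
    def test_independent_taxa_give_empty_network(self):
        rng = np.random.default_rng(0)
        sm = zili.StateMatrix(values=rng.integers(0, 3, (200, 10)), levels=[3] * 10)
        net, _ = neighborhood_select(sm, FitConfig())
        assert net.n_edges <= 1

    def test_perfectly_coupled_pair_detected(self):
        rng = np.random.default_rng(7)
        vals = rng.integers(0, 3, size=(200, 10))
        vals[:, 1] = vals[:, 0]
        sm = zili.StateMatrix(values=vals, levels=[3] * 10)
        net, fits = neighborhood_select(sm, FitConfig())
        assert net.has_edge(net.nodes[0], net.nodes[1])
        assert net.n_edges == 1

    def test_and_rule_is_intersection_of_directions(self):
        rng = np.random.default_rng(12)
        vals = rng.integers(0, 3, size=(150, 6))
        vals[:, 1] = np.where(rng.random(150) < 0.8, vals[:, 0], vals[:, 1])
        sm = zili.StateMatrix(values=vals, levels=[3] * 6)
        net_or, _ = neighborhood_select(sm, FitConfig(edge_rule="or"))
        net_and, _ = neighborhood_select(sm, FitConfig(edge_rule="and"))
        d = net_or.directed_support
        np.testing.assert_array_equal(net_or.adjacency, d | d.T)
        np.testing.assert_array_equal(net_and.adjacency, d & d.T)

    def test_degenerate_taxa_stay_isolated(self):
        rng = np.random.default_rng(13)
        vals = rng.integers(0, 3, size=(100, 5))
        vals[:, 4] = 0
        sm = zili.StateMatrix(values=vals, levels=[3, 3, 3, 3, 1])
        net, fits = neighborhood_select(sm, FitConfig())
        assert not np.any(net.adjacency[4])
        assert 4 not in fits


class TestFitZili:
    def test_sample_order_invariance(self, small_dataset):
        X = small_dataset.abundance
        fit1 = fit_zili(X, FitConfig())
        perm = np.random.default_rng(0).permutation(X.n_samples)
        Xp = zili.AbundanceMatrix(
            values=X.values[perm],
            mode="relative",
            samples=[X.samples[i] for i in perm],
            taxa=list(X.taxa),
        )
        fit2 = fit_zili(Xp, FitConfig())
        np.testing.assert_array_equal(fit1.network.adjacency, fit2.network.adjacency)

    def test_easy_regime_recovers_cycle(self, small_dataset):
        fit = fit_zili(small_dataset.abundance, FitConfig())
        tpr, fpr = zili.tpr_fpr(fit.network, small_dataset.truth)
        assert tpr == 1.0
        assert fpr <= 0.05
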