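"""Edge-wise GLM and NBS permutation test, against independent oracles."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest
from scipy import stats as sps

from conndist.connectome import EdgeIndex
from conndist.nbs import (
    EdgeStatMap,
    NbsConfig,
    NetworkBasedStatistic,
    edge_glm,
    nbs_test,
    suprathreshold_components,
)


def _residualize_oracle_t(edge, outcome, covariates):
    """Independent oracle: residualize edge and outcome on covariates,
    correlate the residuals, convert r to t with df = n - k - 2."""
    n = edge.shape[0]
    Z = np.column_stack([np.ones(n), covariates]) if covariates is not None else np.ones((n, 1))
    re = edge - Z @ np.linalg.lstsq(Z, edge, rcond=None)[0]
    ry = outcome - Z @ np.linalg.lstsq(Z, outcome, rcond=None)[0]
    r = np.corrcoef(re, ry)[0, 1]
    df = n - Z.shape[1] - 1
    return r * np.sqrt(df / (1 - r**2))


class TestEdgeGlm:
    def test_closed_form_t_small_case(self):
        """t = r * sqrt((n-2)/(1-r^2)) for simple correlation, hand-checkable."""
        outcome = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        edge = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        r = np.corrcoef(edge, outcome)[0, 1]
        expected = r * np.sqrt(4 / (1 - r**2))
        stats = edge_glm(edge[:, None], outcome)
        assert stats.t_values[0] == pytest.approx(expected, abs=1e-10)
        assert stats.df == 4

    def test_matches_residualization_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(8, 25))
            k = int(rng.integers(1, 3))
            E = rng.normal(size=(n, 5))
            y = rng.normal(size=n)
            Z = rng.normal(size=(n, k))
            stats = edge_glm(E, y, Z)
            assert stats.df == n - k - 2
            for e in range(5):
                oracle = _residualize_oracle_t(E[:, e], y, Z)
                assert stats.t_values[e] == pytest.approx(oracle, abs=1e-10)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        n = 40
        E = rng.normal(size=(n, 3))
        y = rng.normal(size=n)
        Z = rng.normal(size=(n, 2))
        stats = edge_glm(E, y, Z)
        X = sm.add_constant(np.column_stack([y, Z]))
        for e in range(3):
            fit = sm.OLS(E[:, e], X).fit()
            assert stats.t_values[e] == pytest.approx(fit.tvalues[1], abs=1e-10)

    def test_perfect_fit_saturates(self):
        y = np.arange(10.0)
        stats = edge_glm(y[:, None] * 2 + 1, y)
        assert abs(stats.t_values[0]) > 1e6

    def test_affine_invariance_of_outcome_and_covariates(self, rng):
        n = 30
        E = rng.normal(size=(n, 4))
        y = rng.normal(size=n)
        Z = rng.normal(size=(n, 2))
        t1 = edge_glm(E, y, Z).t_values
        t2 = edge_glm(E, 5 * y - 3, np.column_stack([2 * Z[:, 0] + 1, -Z[:, 1]])).t_values
        assert np.allclose(t1, t2, atol=1e-9)

    def test_constant_edge_warns_t_zero(self, rng):
        E = np.column_stack([np.full(20, 2.0), rng.normal(size=20)])
        with pytest.warns(RuntimeWarning, match="constant edge"):
            stats = edge_glm(E, rng.normal(size=20))
        assert stats.t_values[0] == 0.0

    def test_collinear_covariates_rejected(self, rng):
        Z = rng.normal(size=(20, 1))
        with pytest.raises(ValueError, match="rank-deficient"):
            edge_glm(rng.normal(size=(20, 3)), rng.normal(size=20),
                     np.column_stack([Z, 2 * Z]))

    def test_constant_outcome_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            edge_glm(rng.normal(size=(10, 2)), np.ones(10))


def _stat_map(n_regions, supra_edges, t_value=4.0):
    index = EdgeIndex(n_regions)
    t = np.zeros(len(index))
    for i, j in supra_edges:
        t[index.to_flat(i, j)] = t_value
    return EdgeStatMap(t_values=t, df=10), index


class TestSuprathresholdComponents:
    def test_chain_plus_pair(self):
        stats, index = _stat_map(6, [(0, 1), (1, 2), (3, 4)])
        comps = suprathreshold_components(stats, 3.5)
        sizes = sorted(c.size for c in comps)
        assert sizes == [1, 2]

    def test_empty_when_nothing_exceeds(self):
        stats, _ = _stat_map(6, [(0, 1)], t_value=2.0)
        assert suprathreshold_components(stats, 3.5) == []

    def test_clique_is_one_component(self):
        edges = list(itertools.combinations(range(4), 2))
        stats, _ = _stat_map(6, edges)
        comps = suprathreshold_components(stats, 3.5)
        assert len(comps) == 1
        assert comps[0].size == 6

    def test_partition_property(self, rng):
        """Every suprathreshold edge lands in exactly one component."""
        index = EdgeIndex(12)
        t = rng.normal(size=len(index)) * 3
        stats = EdgeStatMap(t_values=t, df=10)
        comps = suprathreshold_components(stats, 3.0)
        all_edges = np.concatenate(comps) if comps else np.array([], dtype=int)
        assert len(np.unique(all_edges)) == len(all_edges)
        assert set(all_edges) == set(np.flatnonzero(np.abs(t) > 3.0))

    def test_matches_networkx_components(self, rng):
        index = EdgeIndex(15)
        t = rng.normal(size=len(index)) * 2.5
        stats = EdgeStatMap(t_values=t, df=10)
        comps = suprathreshold_components(stats, 2.0)
        g = nx.Graph()
        for flat in np.flatnonzero(np.abs(t) > 2.0):
            g.add_edge(*index.to_pair(int(flat)))
        nx_sizes = sorted(g.subgraph(c).number_of_edges() for c in nx.connected_components(g))
        assert sorted(c.size for c in comps) == nx_sizes


def _brute_force_nbs(E, y, threshold):
    """Independent NBS oracle: per-edge correlation t (no covariates),
    networkx components, exhaustive enumeration of outcome orderings."""
    n, m = E.shape
    R = int((1 + math.isqrt(1 + 8 * m)) / 2)
    pairs = list(itertools.combinations(range(R), 2))

    def t_vec(yy):
        t = np.empty(m)
        for e in range(m):
            r, _ = sps.pearsonr(E[:, e], yy)
            t[e] = r * math.sqrt((n - 2) / (1 - r**2))
        return t

    def components(t):
        g = nx.Graph()
        for e, (i, j) in enumerate(pairs):
            if abs(t[e]) > threshold:
                g.add_edge(i, j, flat=e)
        return [
            sorted(d["flat"] for _, _, d in g.subgraph(c).edges(data=True))
            for c in nx.connected_components(g)
        ]

    obs = components(t_vec(y))
    null_max = []
    for order in itertools.permutations(range(n)):
        cs = components(t_vec(y[list(order)]))
        null_max.append(max((len(c) for c in cs), default=0))
    null_max = np.array(null_max)
    p = {
        tuple(c): float(np.mean(null_max >= len(c)))
        for c in obs
    }
    return obs, p


class TestNbsTest:
    def test_exhaustive_matches_brute_force_exactly(self, rng):
        n = 6  # 720 orderings: exact agreement with the enumeration oracle
        index = EdgeIndex(5)
        E = rng.normal(size=(n, len(index)))
        y = rng.normal(size=n)
        threshold = 1.5
        obs_oracle, p_oracle = _brute_force_nbs(E, y, threshold)
        results = nbs_test(
            E, y, None,
            NbsConfig(t_threshold=threshold, n_permutations=1, alpha=0.05,
                      permutations="exhaustive"),
        )
        assert sorted(tuple(r.edge_indices) for r in results) == sorted(
            tuple(c) for c in obs_oracle
        )
        for r in results:
            assert r.p_fwe == pytest.approx(p_oracle[tuple(r.edge_indices)], abs=1e-12)

    def test_recovers_planted_component(self, planted_cohort):
        config, cohort, truth = planted_cohort
        results = nbs_test(
            cohort.edge_table,
            cohort.outcome(),
            cohort.covariates(),
            NbsConfig(t_threshold=3.0, n_permutations=300, alpha=0.05, seed=1),
        )
        significant = [r for r in results if r.significant]
        assert significant
        found = set(significant[0].edge_list)
        planted = set(truth.effect_edge_list)
        jaccard = len(found & planted) / len(found | planted)
        assert jaccard > 0.5
        # planted correlations are negative, so the component should be too
        assert significant[0].sign_profile["negative"] > significant[0].sign_profile["positive"]

    def test_deterministic_given_seed(self, null_cohort):
        _, cohort, _ = null_cohort
        config = NbsConfig(t_threshold=2.5, n_permutations=50, alpha=0.05, seed=3)
        r1 = nbs_test(cohort.edge_table, cohort.outcome(), None, config)
        r2 = nbs_test(cohort.edge_table, cohort.outcome(), None, config)
        assert [(c.n_edges, c.p_fwe) for c in r1] == [(c.n_edges, c.p_fwe) for c in r2]

    def test_p_fwe_in_unit_interval_and_monotone(self, null_cohort):
        _, cohort, _ = null_cohort
        results = nbs_test(
            cohort.edge_table, cohort.outcome(), None,
            NbsConfig(t_threshold=2.0, n_permutations=100, alpha=0.05, seed=5),
        )
        assert results  # low threshold: something always survives
        for r in results:
            assert 0 < r.p_fwe <= 1
        sizes = [r.size for r in results]
        ps = [r.p_fwe for r in results]
        for (s1, p1), (s2, p2) in itertools.combinations(zip(sizes, ps), 2):
            if s1 > s2:
                assert p1 <= p2

    def test_freedman_lane_scheme_runs(self, null_cohort):
        _, cohort, _ = null_cohort
        results = nbs_test(
            cohort.edge_table, cohort.outcome(), cohort.covariates(),
            NbsConfig(t_threshold=2.5, n_permutations=50, seed=2, scheme="freedman_lane"),
        )
        for r in results:
            assert 0 < r.p_fwe <= 1

    def test_intensity_and_by_sign_variants(self, planted_cohort):
        _, cohort, _ = planted_cohort
        base = dict(t_threshold=3.0, n_permutations=100, alpha=0.05, seed=4)
        extent = nbs_test(cohort.edge_table, cohort.outcome(), None, NbsConfig(**base))
        intensity = nbs_test(
            cohort.edge_table, cohort.outcome(), None,
            NbsConfig(size_measure="intensity", **base),
        )
        by_sign = nbs_test(
            cohort.edge_table, cohort.outcome(), None,
            NbsConfig(component_mode="by_sign", **base),
        )
        assert extent and intensity and by_sign
        # by-sign components are sign-pure
        for r in by_sign:
            assert r.sign_profile["positive"] == 0 or r.sign_profile["negative"] == 0


class TestEstimator:
    def test_fit_transform_selects_component(self, planted_cohort):
        _, cohort, truth = planted_cohort
        est = NetworkBasedStatistic(
            t_threshold=3.0, n_permutations=200, alpha=0.05, random_state=0
        )
        feature = est.fit_transform(
            cohort.edge_table, cohort.outcome(), covariates=cohort.covariates()
        )
        assert feature.shape == (cohort.n_subjects, 1)
        assert est.component_ is not None
        support = est.get_support()
        assert support.sum() == est.component_.n_edges
        manual = cohort.edge_table[:, support].mean(axis=1)
        assert np.allclose(feature.ravel(), manual)

    def test_get_set_params_round_trip(self):
        est = NetworkBasedStatistic()
        params = est.get_params()
        est.set_params(t_threshold=2.0, alpha=0.05)
        assert est.get_params()["t_threshold"] == 2.0
        with pytest.raises(ValueError):
            est.set_params(bogus=1)

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        est = NetworkBasedStatistic(t_threshold=2.5)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
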