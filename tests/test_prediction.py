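"""Component feature extraction and repeated cross-validated prediction."""

import numpy as np
import pytest

from conndist.connectome import EdgeIndex
from conndist.nbs import ComponentResult, NbsConfig
from conndist.prediction import (
    CVConfig,
    _fold_ids,
    component_feature,
    cv_predict,
    nested_cv_predict,
)


def _component(index, pairs):
    flat = np.array([index.to_flat(i, j) for i, j in pairs])
    return ComponentResult(
        edge_list=list(pairs), edge_indices=flat, n_edges=len(pairs),
        sign_profile={}, p_fwe=0.01, significant=True, size=float(len(pairs)),
    )


class TestComponentFeature:
    def test_single_edge_is_that_edge(self, rng):
        index = EdgeIndex(5)
        E = rng.normal(size=(10, len(index)))
        comp = _component(index, [(1, 3)])
        flat = index.to_flat(1, 3)
        assert np.allclose(component_feature(E, comp), E[:, flat])

    def test_mean_of_two_edges(self):
        index = EdgeIndex(3)
        E = np.array([[0.2, 0.4, 99.0]])  # edges (0,1), (0,2), (1,2)
        comp = _component(index, [(0, 1), (0, 2)])
        assert component_feature(E, comp)[0] == pytest.approx(0.3)

    def test_invariant_to_edge_order(self, rng):
        index = EdgeIndex(6)
        E = rng.normal(size=(8, len(index)))
        pairs = [(0, 1), (2, 3), (4, 5)]
        f1 = component_feature(E, _component(index, pairs))
        f2 = component_feature(E, _component(index, pairs[::-1]))
        assert np.allclose(f1, f2)

    def test_empty_component_rejected(self):
        comp = ComponentResult(edge_list=[], edge_indices=np.array([], dtype=int),
                               n_edges=0, sign_profile={}, p_fwe=1.0)
        with pytest.raises(ValueError, match="empty"):
            component_feature(np.zeros((5, 10)), comp)


class TestFoldAssignment:
    @pytest.mark.parametrize("n, k", [(100, 10), (25, 10), (47, 5)])
    def test_balanced_folds(self, n, k, rng):
        fold = _fold_ids(n, k, rng)
        counts = np.bincount(fold, minlength=k)
        assert counts.sum() == n
        assert counts.max() - counts.min() <= 1


class TestCvPredict:
    def test_noiseless_linear_recovery(self, rng):
        x = rng.normal(size=100)
        y = 3.0 * x - 1.0
        res = cv_predict(x, y, CVConfig(n_repeats=5, n_null_permutations=0, seed=0))
        assert res.r_predicted_actual == pytest.approx(1.0, abs=1e-9)
        assert res.p_permutation is None

    def test_final_r_is_mean_of_repeats(self, rng):
        x = rng.normal(size=60)
        y = 0.5 * x + rng.normal(size=60)
        res = cv_predict(x, y, CVConfig(n_repeats=8, n_null_permutations=0, seed=1))
        assert res.r_predicted_actual == pytest.approx(res.per_repeat_r.mean())
        assert res.per_repeat_r.shape == (8,)

    def test_deterministic_given_seed(self, rng):
        x = rng.normal(size=50)
        y = 0.4 * x + rng.normal(size=50)
        cfg = CVConfig(n_repeats=5, n_null_permutations=20, seed=9)
        r1 = cv_predict(x, y, cfg)
        r2 = cv_predict(x, y, cfg)
        assert r1.r_predicted_actual == r2.r_predicted_actual
        assert r1.p_permutation == r2.p_permutation

    def test_signal_detected_with_small_p(self, rng):
        n = 100
        x = rng.normal(size=n)
        y = x + 0.8 * rng.normal(size=n)  # pop r ~ 0.78
        res = cv_predict(x, y, CVConfig(n_repeats=10, n_null_permutations=99, seed=4))
        assert res.r_predicted_actual > 0.5
        assert res.p_permutation == pytest.approx(1 / 100)

    def test_null_feature_r_near_zero(self, rng):
        x = rng.normal(size=100)
        y = rng.normal(size=100)
        res = cv_predict(x, y, CVConfig(n_repeats=10, n_null_permutations=0, seed=2))
        assert abs(res.r_predicted_actual) < 0.35

    def test_cv_r_below_in_sample_r_for_signal(self, rng):
        """The CV machinery itself must not leak: out-of-sample r does not
        beat the in-sample correlation (on average over repeats)."""
        n = 100
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        in_sample = abs(np.corrcoef(x, y)[0, 1])
        res = cv_predict(x, y, CVConfig(n_repeats=30, n_null_permutations=0, seed=3))
        assert res.r_predicted_actual <= in_sample + 0.02

    def test_constant_feature_warns_and_scores_zero(self):
        x = np.ones(40)
        y = np.random.default_rng(0).normal(size=40)
        with pytest.warns(RuntimeWarning, match="constant training feature"):
            res = cv_predict(x, y, CVConfig(n_folds=2, n_repeats=2, n_null_permutations=0))
        # folds fall back to the training mean: no real predictive signal
        assert abs(res.r_predicted_actual) < 0.3

    def test_pooling_conventions_differ_under_null(self, rng):
        """Pooled-prediction r is negatively biased under the null (fold
        intercepts anticorrelate with held-out outcomes); per-fold
        averaging is centered at zero."""
        rs_pf, rs_pl = [], []
        for i in range(40):
            x = rng.normal(size=100)
            y = rng.normal(size=100)
            base = dict(n_repeats=3, n_null_permutations=0, seed=i)
            rs_pf.append(cv_predict(x, y, CVConfig(**base)).r_predicted_actual)
            rs_pl.append(
                cv_predict(x, y, CVConfig(pooling="pooled", **base)).r_predicted_actual
            )
        assert abs(np.mean(rs_pf)) < 0.08
        assert np.mean(rs_pl) < -0.08

    def test_residualize_requires_covariates(self, rng):
        with pytest.raises(ValueError, match="covariates"):
            cv_predict(rng.normal(size=40), rng.normal(size=40),
                       CVConfig(n_folds=2, n_repeats=1, n_null_permutations=0),
                       residualize=True)

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError, match="subjects"):
            cv_predict(rng.normal(size=15), rng.normal(size=15), CVConfig())


def test_nested_cv_is_more_conservative_on_null(null_cohort):
    """On a null cohort, re-identifying the component inside each training
    fold cannot manufacture signal."""
    _, cohort, _ = null_cohort
    res = nested_cv_predict(
        cohort.edge_table,
        cohort.outcome(),
        nbs_config=NbsConfig(t_threshold=2.5, n_permutations=20, alpha=0.5,
                             seed=0),
        n_folds=5,
        seed=1,
    )
    assert abs(res.r_predicted_actual) < 0.45
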