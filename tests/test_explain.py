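"""Shapley attribution estimator, permutation importance, and the
Shapley-ranked feature selection."""

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression
from sklearn.tree import DecisionTreeClassifier

from cardioresp.explain import (
    permutation_importance,
    select_top_features,
    shapley_attributions,
)


class _LinearScore:
    """Deterministic linear scorer f(x) = x @ W (decision-function only)."""

    def __init__(self, W):
        self.W = np.asarray(W, dtype=float)

    def decision_function(self, X):
        return np.asarray(X) @ self.W


class TestShapley:
    def test_linear_model_closed_form(self, rng):
        """phi_j = w_j (x_j - E[background_j]) for a linear scorer.

        The background is tightly concentrated so the Monte-Carlo draw of
        background rows contributes negligible sampling error and the
        closed form can be checked at the estimator tolerance.
        """
        W = np.array([[1.0], [-2.0], [0.5], [0.0]])
        model = _LinearScore(W)
        center = np.array([0.3, -0.1, 0.8, 0.2])
        bg = center + 0.005 * rng.standard_normal((80, 4))
        x = rng.standard_normal((3, 4))
        phi, base = shapley_attributions(model, x, bg, n_permutations=200, seed=0)
        for i in range(3):
            expected = W[:, 0] * (x[i] - bg.mean(axis=0))
            assert np.allclose(phi[i, :, 0], expected, atol=0.02)

    def test_zero_weight_feature_gets_zero_attribution(self, rng):
        model = _LinearScore(np.array([[1.0], [0.0]]))
        bg = rng.standard_normal((50, 2))
        phi, _ = shapley_attributions(model, rng.standard_normal((5, 2)), bg,
                                      n_permutations=100, seed=1)
        assert np.all(np.abs(phi[:, 1, 0]) <= 0.01)

    def test_local_additivity_holds(self, rng):
        X = rng.standard_normal((120, 5))
        y = (X[:, 0] + 0.5 * X[:, 1] > 0).astype(int)
        clf = LogisticRegression(max_iter=500).fit(X, y)
        x_test = rng.standard_normal((50, 5))
        phi, base = shapley_attributions(clf, x_test, X, n_permutations=8, seed=2)
        out = clf.predict_proba(x_test)
        recon = phi.sum(axis=1) + base
        assert np.allclose(recon, out, atol=0.02)

    def test_seed_determinism(self, rng):
        model = _LinearScore(np.array([[1.0], [2.0]]))
        bg = rng.standard_normal((30, 2))
        x = rng.standard_normal((4, 2))
        a, _ = shapley_attributions(model, x, bg, n_permutations=20, seed=9)
        b, _ = shapley_attributions(model, x, bg, n_permutations=20, seed=9)
        assert np.array_equal(a, b)

    def test_empty_background_rejected(self, rng):
        with pytest.raises(ValueError):
            shapley_attributions(_LinearScore([[1.0]]),
                                 rng.standard_normal((2, 1)),
                                 np.empty((0, 1)))


class TestPermutationImportance:
    @staticmethod
    def _fit_stump(rng, n=400):
        X = rng.standard_normal((n, 4))
        y = (X[:, 0] > 0).astype(int)
        model = DecisionTreeClassifier(max_depth=1, random_state=0).fit(X, y)
        return model, X, y

    def test_unused_feature_importance_near_zero(self, rng):
        model, X, y = self._fit_stump(rng)
        imp = permutation_importance(model, X, y, rounds=30, seed=0)
        assert abs(imp.iloc[3]["0_mean"]) <= 0.01
        assert abs(imp.iloc[3]["1_mean"]) <= 0.01

    def test_sole_informative_feature_ranks_first(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            model, X, y = self._fit_stump(rng)
            imp = permutation_importance(model, X, y, rounds=10, seed=seed)
            assert imp["1_mean"].idxmax() == 0

    def test_importance_sd_nonnegative_and_deterministic(self, rng):
        model, X, y = self._fit_stump(rng)
        a = permutation_importance(model, X, y, rounds=5, seed=3)
        b = permutation_importance(model, X, y, rounds=5, seed=3)
        assert (a.filter(like="_sd") >= 0).all().all()
        assert a.equals(b)


class TestSelectTopFeatures:
    def test_identity_selection_when_k_equals_count(self, rng):
        phi = rng.standard_normal((20, 6, 3))
        names = [f"f{i}" for i in range(6)]
        assert set(select_top_features(phi, names, k=6)) == set(names)

    def test_planted_informative_features_rank_high(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((300, 20))
            w = np.zeros(20)
            w[:5] = 3.0
            y = (X @ w + 0.5 * rng.standard_normal(300) > 0).astype(int)
            clf = LogisticRegression(max_iter=500).fit(X, y)
            phi, _ = shapley_attributions(clf, X[:40], X, n_permutations=10,
                                          seed=seed)
            top10 = select_top_features(phi, [f"f{i}" for i in range(20)], k=10)
            if all(f"f{i}" in top10 for i in range(5)):
                hits += 1
        assert hits >= 9

    def test_selection_length_is_35(self, rng):
        phi = rng.standard_normal((10, 60, 3))
        out = select_top_features(phi, [f"f{i}" for i in range(60)], k=35)
        assert len(out) == 35

    def test_k_exceeding_feature_count_rejected(self, rng):
        with pytest.raises(ValueError):
            select_top_features(rng.standard_normal((5, 4, 2)),
                                ["a", "b", "c", "d"], k=5)

    def test_selection_stable_across_seeds(self):
        """Jaccard overlap of top-35 across two seeds on 40 planted signals."""
        sets = []
        for seed in (0, 1):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((400, 80))
            w = np.zeros(80)
            w[:40] = rng.uniform(1.0, 2.0, 40)
            y = (X @ w + rng.standard_normal(400) > 0).astype(int)
            clf = LogisticRegression(max_iter=500).fit(X, y)
            phi, _ = shapley_attributions(clf, X[:60], X, n_permutations=8,
                                          seed=seed)
            sets.append(set(select_top_features(
                phi, [f"f{i}" for i in range(80)], k=35)))
        jaccard = len(sets[0] & sets[1]) / len(sets[0] | sets[1])
        assert jaccard >= 0.6
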