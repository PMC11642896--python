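"""Dataset assembly, SMOTE contract, cross-validation leakage guards, and
the between-dataset statistical comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cardioresp.manifest import default_manifest
from cardioresp.modeling import (
    DATASET_SPECS,
    GROUP_ORDER,
    assemble_dataset,
    compare_datasets,
    default_model_zoo,
    demographic_tests,
    reduced_spec,
    run_cv,
)
from cardioresp.smote import smote_resample


@pytest.fixture(scope="module")
def fake_feature_table():
    """Random-valued table with the full manifest schema (45 subjects)."""
    manifest = default_manifest()
    rng = np.random.default_rng(0)
    n = 45
    data = {name: rng.standard_normal(n) for name in manifest.names}
    table = pd.DataFrame(data, index=[f"S{i:03d}" for i in range(n)])
    table.insert(0, "group", [GROUP_ORDER[i % 3] for i in range(n)])
    table.index.name = "subject_id"
    return table


def _clusters(rng, n_per=20, sep=10.0, d=6):
    """Linearly separable 3-class clusters (separation ~10 sigma)."""
    X, y = [], []
    for c in range(3):
        center = np.zeros(d)
        center[c % d] = sep * c
        X.append(center + rng.standard_normal((n_per, d)))
        y += [c] * n_per
    return np.vstack(X), np.array(y)


class TestAssembleDataset:
    @pytest.mark.parametrize("ds,count", [("D1", 107), ("D2", 125),
                                          ("D3", 157), ("D4", 152)])
    def test_column_counts_match_dataset_design(self, fake_feature_table, ds, count):
        X, y = assemble_dataset(fake_feature_table, DATASET_SPECS[ds])
        assert X.shape == (45, count)
        assert set(y) == {0, 1, 2}

    def test_reduced_dataset_has_35_columns(self, fake_feature_table):
        manifest = default_manifest()
        subset = manifest.names_for(*DATASET_SPECS["D3"].included_domains)[:35]
        X, _ = assemble_dataset(fake_feature_table,
                                reduced_spec("D5", "D3", subset))
        assert X.shape[1] == 35

    def test_unknown_subset_feature_rejected(self, fake_feature_table):
        with pytest.raises(ValueError):
            assemble_dataset(fake_feature_table,
                             reduced_spec("D5", "D3", ["NoSuchFeature"]))


class TestSmote:
    def test_strategy_200_each_gives_600_rows(self, rng):
        X = rng.standard_normal((26 + 56 + 40, 5))
        y = np.array([0] * 26 + [1] * 56 + [2] * 40)
        X2, y2 = smote_resample(X, y, {0: 200, 1: 200, 2: 200}, seed=0)
        assert len(X2) == 600
        assert list(np.bincount(y2)) == [200, 200, 200]
        assert np.array_equal(X2[: len(X)], X)  # originals preserved first

    def test_synthetic_points_lie_on_parent_segments(self, rng):
        X = rng.standard_normal((8, 3))
        y = np.zeros(8, dtype=int)
        X2, _ = smote_resample(X, y, {0: 30}, seed=1)
        for z in X2[8:]:
            ok = False
            for i in range(8):
                for j in range(8):
                    if i == j:
                        continue
                    seg = X[j] - X[i]
                    u = np.dot(z - X[i], seg) / np.dot(seg, seg)
                    if 0.0 <= u <= 1.0 and \
                            np.linalg.norm(z - (X[i] + u * seg)) < 1e-9:
                        ok = True
            assert ok

    def test_matching_strategy_is_noop(self, rng):
        X = rng.standard_normal((10, 4))
        y = np.array([0] * 4 + [1] * 6)
        X2, y2 = smote_resample(X, y, {0: 4, 1: 6}, seed=0)
        assert np.array_equal(X2, X) and np.array_equal(y2, y)

    def test_below_count_strategy_rejected(self, rng):
        X = rng.standard_normal((10, 2))
        y = np.array([0] * 4 + [1] * 6)
        with pytest.raises(ValueError):
            smote_resample(X, y, {0: 2}, seed=0)

    def test_absent_class_rejected(self, rng):
        X = rng.standard_normal((6, 2))
        y = np.zeros(6, dtype=int)
        with pytest.raises(ValueError):
            smote_resample(X, y, {1: 10}, seed=0)


class TestRunCV:
    def test_each_subject_in_exactly_one_test_fold(self, rng):
        X, y = _clusters(rng)
        report = run_cv(X, y, default_model_zoo(0, ["nb"]), k=5, seed=0)
        seen = np.concatenate(report.folds)
        assert sorted(seen) == list(range(len(y)))

    def test_separable_clusters_reach_high_accuracy(self, rng):
        X, y = _clusters(rng, sep=10.0)
        report = run_cv(X, y, default_model_zoo(0, ["logreg"]), k=10, seed=0)
        assert report.per_model["logreg"].mean_metric("accuracy") >= 0.98

    def test_fold_metrics_counted_and_confusion_pooled(self, rng):
        X, y = _clusters(rng)
        report = run_cv(X, y, default_model_zoo(0, ["nb"]), k=5, seed=0)
        res = report.per_model["nb"]
        assert len(res.fold_metrics) == 5
        assert res.pooled_confusion.sum() == len(y)

    def test_nan_features_are_imputed_within_folds(self, rng):
        X, y = _clusters(rng)
        X[::7, 0] = np.nan
        report = run_cv(X, y, default_model_zoo(0, ["nb"]), k=5, seed=0)
        assert report.per_model["nb"].fold_metrics  # no fold failed


class TestCompareDatasets:
    def test_self_comparison_is_one(self):
        vals = {"D1": [0.5] * 10, "D2": [0.5] * 10}
        mat = compare_datasets(vals)
        assert mat.loc["D1", "D1"] == 1.0
        assert mat.loc["D1", "D2"] == 1.0  # identical -> tie

    def test_constant_shift_exact_signed_rank_p(self):
        rng = np.random.default_rng(0)
        base = rng.random(10)
        mat = compare_datasets({"A": list(base), "B": list(base + 1.0)})
        assert mat.loc["A", "B"] == pytest.approx(0.002, abs=0.0005)

    def test_matrix_symmetric(self):
        rng = np.random.default_rng(1)
        vals = {k: list(rng.random(10)) for k in ("A", "B", "C")}
        mat = compare_datasets(vals)
        assert np.allclose(mat.to_numpy(), mat.to_numpy().T)


class TestDemographicTests:
    @staticmethod
    def _cohort(rng, shift=0.0):
        rows = []
        for g in GROUP_ORDER:
            for _ in range(20):
                rows.append({
                    "group": g,
                    "age": rng.normal(12 + (shift if g == "Sport" else 0), 2),
                    "weight_kg": rng.normal(50, 10),
                    "height_cm": rng.normal(160, 10),
                    "bmi": rng.normal(20, 2),
                })
        return pd.DataFrame(rows)

    def test_null_rejection_rate_near_alpha(self):
        rejections = 0
        trials = 200
        for s in range(trials):
            res = demographic_tests(self._cohort(np.random.default_rng(s)))
            if res.loc["age", "p"] < 0.05:
                rejections += 1
        assert 0.01 <= rejections / trials <= 0.12

    def test_large_shift_detected(self, rng):
        res = demographic_tests(self._cohort(rng, shift=10.0))
        assert res.loc["age", "p"] < 1e-6

    def test_two_groups_rejected(self, rng):
        cohort = self._cohort(rng)
        with pytest.raises(ValueError):
            demographic_tests(cohort[cohort["group"] != "Sport"])
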