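import numpy as np
import pytest
import scipy.stats
from sklearn.metrics import precision_recall_fscore_support
from sklearn.neighbors import KNeighborsClassifier

from fracsel import (
    LabeledDataset,
    confusion_and_metrics,
    correlation_summary,
    evaluate_with_classifier,
    make_classifier,
    pearson_r,
    run_grid,
)


class TestConfusionAndMetrics:
    def test_perfect_prediction(self, rng):
        y = rng.integers(0, 3, size=30)
        report = confusion_and_metrics(y, y)
        assert report.accuracy == report.precision == report.recall == report.f1 == 1.0

    def test_binary_cells_direct_substitution(self):
        # positive class: TP=8, TN=5, FP=2, FN=1
        y_true = np.array([1] * 9 + [0] * 7)
        y_pred = np.array([1] * 8 + [0] * 1 + [0] * 5 + [1] * 2)
        report = confusion_and_metrics(y_true, y_pred)
        pos = next(c for c in report.per_class if c.label == 1)
        assert (pos.tp, pos.tn, pos.fp, pos.fn) == (8, 5, 2, 1)
        assert report.accuracy == pytest.approx(13 / 16)
        assert pos.precision == pytest.approx(0.8)
        assert pos.recall == pytest.approx(8 / 9)
        assert pos.f1 == pytest.approx(2 * (0.8 * 8 / 9) / (0.8 + 8 / 9))

    def test_matches_sklearn_macro_oracle(self, rng):
        y_true = rng.integers(0, 3, size=60)
        y_pred = rng.integers(0, 3, size=60)
        report = confusion_and_metrics(y_true, y_pred)
        prec, rec, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, average="macro", zero_division=0
        )
        assert report.precision == pytest.approx(prec, abs=1e-12)
        assert report.recall == pytest.approx(rec, abs=1e-12)
        assert report.f1 == pytest.approx(f1, abs=1e-12)
        assert report.accuracy == pytest.approx(np.mean(y_true == y_pred))

    def test_bounds_and_f1_identity_on_random_predictions(self, rng):
        for _ in range(500):
            n = int(rng.integers(1, 30))
            k = int(rng.integers(1, 5))
            y_true = rng.integers(0, k, size=n)
            y_pred = rng.integers(0, k, size=n)
            report = confusion_and_metrics(y_true, y_pred)
            for value in (report.accuracy, report.precision, report.recall, report.f1):
                assert 0.0 <= value <= 1.0
            for c in report.per_class:
                if c.precision + c.recall > 0:
                    expected = 2 * c.precision * c.recall / (c.precision + c.recall)
                    assert c.f1 == pytest.approx(expected, abs=1e-12)
                else:
                    assert c.f1 == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_and_metrics([0, 1], [0, 1, 1])


class TestPearson:
    def test_perfect_positive_and_negative(self, rng):
        x = rng.normal(size=10)
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_matches_scipy_oracle(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        assert pearson_r(x, y) == pytest.approx(scipy.stats.pearsonr(x, y).statistic, abs=1e-12)

    def test_constant_input_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            assert pearson_r(np.ones(5), np.arange(5.0)) == 0.0

    def test_symmetry_bounds_and_affine_invariance(self, rng):
        for _ in range(50):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            r = pearson_r(x, y)
            assert -1.0 <= r <= 1.0
            assert r == pytest.approx(pearson_r(y, x), abs=1e-12)
            assert pearson_r(3.0 * x + 5.0, y) == pytest.approx(r, abs=1e-9)


class TestCorrelationSummary:
    @staticmethod
    def _dataset(values, labels):
        return LabeledDataset(
            values=values,
            feature_ids=[f"f{j}" for j in range(values.shape[1])],
            instance_ids=[str(i) for i in range(values.shape[0])],
            labels=labels,
        )

    def test_degenerate_perfect_case(self):
        col = np.array([0.0, 1, 0, 1, 0, 1])
        ds = self._dataset(np.column_stack([col, col]), col.astype(int))
        summary = correlation_summary(ds, [0, 1])
        assert summary.feature_feature == pytest.approx(1.0)
        assert summary.feature_label == pytest.approx(1.0)
        assert summary.overall == pytest.approx(1.0)

    def test_overall_is_absolute_average(self, rng):
        ds = self._dataset(rng.uniform(size=(20, 6)), rng.integers(0, 2, size=20))
        summary = correlation_summary(ds, range(6))
        assert summary.overall == pytest.approx(
            (abs(summary.feature_feature) + abs(summary.feature_label)) / 2, abs=1e-15
        )

    def test_exhaustive_pairs_match_large_budget(self, rng):
        ds = self._dataset(rng.uniform(size=(15, 10)), rng.integers(0, 2, size=15))
        a = correlation_summary(ds, range(10), pair_budget=10**9, seed=0)
        b = correlation_summary(ds, range(10), pair_budget=45, seed=0)  # 45 = all pairs
        assert a.feature_feature == pytest.approx(b.feature_feature, abs=1e-12)

    def test_sampled_path_is_seeded_and_close(self, rng):
        ds = self._dataset(rng.uniform(size=(15, 12)), rng.integers(0, 2, size=15))
        a = correlation_summary(ds, range(12), pair_budget=30, seed=5)
        b = correlation_summary(ds, range(12), pair_budget=30, seed=5)
        assert a.feature_feature == b.feature_feature

    def test_empty_subset_rejected(self, rng):
        ds = self._dataset(rng.uniform(size=(5, 3)), np.zeros(5, dtype=int))
        with pytest.raises(ValueError):
            correlation_summary(ds, [])


class TestClassifierHarness:
    @staticmethod
    def _dataset(values, labels):
        return LabeledDataset(
            values=values,
            feature_ids=[f"f{j}" for j in range(values.shape[1])],
            instance_ids=[str(i) for i in range(values.shape[0])],
            labels=np.asarray(labels),
        )

    def test_majority_baseline_on_imbalanced_test(self, rng):
        train = self._dataset(rng.uniform(size=(20, 3)), [1] * 15 + [0] * 5)
        test = self._dataset(rng.uniform(size=(10, 3)), [1] * 9 + [0] * 1)
        report = evaluate_with_classifier(train, test, make_classifier("majority"))
        assert report.accuracy == pytest.approx(0.9)

    def test_one_nearest_neighbor_memorizes(self, rng):
        train = self._dataset(rng.uniform(size=(12, 4)), rng.integers(0, 2, size=12))
        test = train.subset_instances(np.arange(6))
        report = evaluate_with_classifier(train, test, KNeighborsClassifier(n_neighbors=1))
        assert report.accuracy == 1.0

    def test_feature_id_mismatch_is_contract_error(self, rng):
        train = self._dataset(rng.uniform(size=(8, 3)), rng.integers(0, 2, size=8))
        test = self._dataset(rng.uniform(size=(4, 3)), rng.integers(0, 2, size=4))
        test.feature_ids = ["x", "y", "z"]
        with pytest.raises(ValueError, match="feature_ids"):
            evaluate_with_classifier(train, test, make_classifier("nb"))

    def test_unknown_classifier_name(self):
        with pytest.raises(ValueError, match="unknown classifier"):
            make_classifier("mlp")


class TestRunGrid:
    def test_grid_shape_and_degenerate_cell(self, default_scenario):
        dataset, _ = default_scenario
        clf = make_classifier("knn")
        table = run_grid(dataset, [2, 3], [5, 10, 20], clf, seed=11)
        assert len(table) == 6
        single = run_grid(dataset, [2], [10], make_classifier("knn"), seed=11)
        row = table[(table.n_blocks == 2) & (table.percent == 10)].iloc[0]
        assert row.accuracy == pytest.approx(single.iloc[0].accuracy)

    def test_best_row_matches_manual_scan(self, default_scenario):
        dataset, _ = default_scenario
        table = run_grid(dataset, [2], [5, 20], make_classifier("nb"), seed=3)
        best = table.loc[table["accuracy"].idxmax()]
        assert best.accuracy == max(table.accuracy)
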