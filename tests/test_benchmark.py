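"""Classifier benchmark: splits, evaluation contracts, the 12-model grid."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gazecomplexity import BenchmarkSpec, run_benchmark, split_train_test, train_eval
from gazecomplexity.benchmark import reports_to_frame, save_reports
from gazecomplexity.tables import FeatureTable


def _blob_table(n_per_class=40, n_features=4, sep=6.0, seed=0, n_participants=10):
    """Three Gaussian blobs, one per activity, optionally well separated."""
    rng = np.random.default_rng(seed)
    rows = []
    activities = ("reading", "watching", "typing")
    for c, activity in enumerate(activities):
        x = rng.normal(c * sep, 1.0, size=(n_per_class, n_features))
        for i in range(n_per_class):
            rows.append(
                {
                    "participant_id": f"P{i % n_participants}",
                    "activity_label": activity,
                    "window_index": i,
                    **{f"f{k}": x[i, k] for k in range(n_features)},
                }
            )
    return FeatureTable(values=pd.DataFrame(rows))


class TestSplit:
    def test_80_20_partition(self):
        table = _blob_table(n_per_class=50)
        train, test = split_train_test(table, seed=1)
        assert len(train) == 120 and len(test) == 30
        merged = pd.concat([train, test])
        assert len(merged) == table.n_rows
        assert not set(train.index) & set(test.index)

    def test_same_seed_identical_split(self):
        table = _blob_table()
        t1, s1 = split_train_test(table, seed=5)
        t2, s2 = split_train_test(table, seed=5)
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(s1, s2)

    def test_stratified_by_activity(self):
        table = _blob_table(n_per_class=45)
        _, test = split_train_test(table, seed=2)
        counts = test["activity_label"].value_counts()
        assert (abs(counts - 9) <= 1).all()

    def test_group_split_keeps_participants_apart(self):
        table = _blob_table()
        train, test = split_train_test(table, seed=3, group_by_participant=True)
        assert not set(train["participant_id"]) & set(test["participant_id"])

    def test_too_few_rows_rejected(self):
        table = _blob_table(n_per_class=4)
        with pytest.raises(ValueError, match="at least 5"):
            split_train_test(table)


class TestTrainEval:
    @pytest.mark.parametrize("method", ["SVM", "DT", "RF"])
    def test_separable_blobs_are_perfectly_classified(self, method):
        table = _blob_table(sep=8.0)
        train, test = split_train_test(table, seed=0)
        accuracy, confusion = train_eval(method, train, test, table.feature_names, seed=0)
        assert accuracy == pytest.approx(100.0)
        off_diag = confusion.to_numpy() - np.diag(np.diag(confusion.to_numpy()))
        assert np.all(off_diag == 0.0)

    def test_confusion_cells_sum_to_100(self):
        table = _blob_table(sep=1.0)
        train, test = split_train_test(table, seed=1)
        accuracy, confusion = train_eval("DT", train, test, table.feature_names, seed=1)
        assert confusion.to_numpy().sum() == pytest.approx(100.0, abs=0.01)
        assert accuracy == pytest.approx(np.trace(confusion.to_numpy()), abs=1e-9)

    def test_permuted_labels_score_at_chance(self):
        """With labels shuffled, mean accuracy over 20 splits is ~33.3%."""
        table = _blob_table(n_per_class=60, sep=6.0, seed=4)
        rng = np.random.default_rng(7)
        permuted = table.values.copy()
        permuted["activity_label"] = rng.permutation(permuted["activity_label"].to_numpy())
        permuted["window_index"] = np.arange(len(permuted))  # keep row keys unique
        table_null = FeatureTable(values=permuted)
        accuracies = []
        for rep in range(20):
            train, test = split_train_test(table_null, seed=rep)
            accuracy, _ = train_eval("DT", train, test, table_null.feature_names, seed=rep)
            accuracies.append(accuracy)
        assert abs(np.mean(accuracies) - 100.0 / 3.0) <= 5.0

    def test_unseen_label_rejected(self):
        table = _blob_table()
        train, test = split_train_test(table, seed=0)
        train = train[train["activity_label"] != "typing"]
        with pytest.raises(ValueError, match="typing"):
            train_eval("RF", train, test, table.feature_names)

    def test_missing_values_imputed_from_train(self):
        table = _blob_table(sep=8.0)
        table.values.iloc[::7, table.values.columns.get_loc("f0")] = np.nan
        train, test = split_train_test(table, seed=0)
        accuracy, _ = train_eval("DT", train, test, table.feature_names, seed=0)
        assert accuracy > 90.0


class TestRunBenchmark:
    @pytest.fixture(scope="class")
    def grid(self):
        tables = {
            "conventional_all": _blob_table(sep=1.5, seed=0),
            "conventional_screened": _blob_table(sep=1.5, seed=0, n_features=2),
            "complexity_all": _blob_table(sep=6.0, seed=1),
            "complexity_screened": _blob_table(sep=6.0, seed=1, n_features=2),
        }
        spec = BenchmarkSpec(base_seed=42, n_replications=6)
        return spec, tables, run_benchmark(spec, tables)

    def test_twelve_configurations(self, grid):
        spec, _, reports = grid
        assert spec.n_configurations == 12
        assert len(reports) == 12

    def test_six_accuracies_per_report(self, grid):
        _, _, reports = grid
        assert all(len(r.accuracies) == 6 for r in reports)

    def test_accuracy_equals_diagonal_of_mean_confusion(self, grid):
        _, _, reports = grid
        for r in reports:
            assert r.accuracy_mean == pytest.approx(
                np.trace(r.confusion_mean.to_numpy()), abs=1e-9
            )

    def test_full_benchmark_deterministic(self, grid):
        spec, tables, reports = grid
        again = run_benchmark(spec, tables)
        for r1, r2 in zip(reports, again):
            np.testing.assert_array_equal(r1.accuracies, r2.accuracies)
            pd.testing.assert_frame_equal(r1.confusion_mean, r2.confusion_mean)

    def test_report_frame_and_json(self, grid, tmp_path):
        _, _, reports = grid
        frame = reports_to_frame(reports)
        assert len(frame) == 12
        assert set(frame["method"]) == {"SVM", "DT", "RF"}
        path = save_reports(reports, tmp_path / "bench.json")
        import json

        payload = json.loads(path.read_text())
        assert len(payload) == 12
        assert all(len(item["accuracies_percent"]) == 6 for item in payload)

    def test_missing_table_rejected(self):
        spec = BenchmarkSpec()
        with pytest.raises(ValueError, match="missing feature table"):
            run_benchmark(spec, {"conventional_all": _blob_table()})

    def test_shuffled_test_features_drop_to_chance(self):
        """Nonsense test features score at chance (no leakage through eval)."""
        table = _blob_table(n_per_class=60, sep=6.0)
        train, test = split_train_test(table, seed=0)
        rng = np.random.default_rng(0)
        accuracies = []
        for rep in range(10):
            shuffled = test.copy()
            for col in table.feature_names:
                shuffled[col] = rng.permutation(shuffled[col].to_numpy())
            accuracy, _ = train_eval("RF", train, shuffled, table.feature_names, seed=rep)
            accuracies.append(accuracy)
        assert abs(np.mean(accuracies) - 100.0 / 3.0) <= 10.0

    def test_train_side_screening(self):
        """With screen_sources, screening happens inside each training split."""
        rng = np.random.default_rng(9)
        table = _blob_table(n_per_class=60, sep=0.0, seed=9)
        # one genuinely informative feature among junk
        acts = table.values["activity_label"].to_numpy()
        shift = {"reading": 0.0, "watching": 4.0, "typing": 8.0}
        table.values["f0"] = rng.normal([shift[a] for a in acts], 1.0)
        spec = BenchmarkSpec(
            methods=("DT",), feature_sets=("conventional_screened",),
            base_seed=0, n_replications=3,
        )
        reports = run_benchmark(
            spec,
            {"conventional_screened": table},
            screen_sources={"conventional_screened": table},
        )
        assert reports[0].n_features < table.n_features  # junk screened out
        assert reports[0].accuracy_mean > 90.0  # the real feature survived

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            BenchmarkSpec(methods=("SVM", "CNN"))
        with pytest.raises(ValueError):
            BenchmarkSpec(test_fraction=1.5)
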