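import numpy as np
import pandas as pd
import pytest

from neurotriage import (
    ClassifierConfig,
    EvaluationReport,
    chronological_order,
    cross_validate,
    evaluate,
    fit_classifier,
    grid_search,
    time_ordered_split,
)
from neurotriage.model_eval import CVReport


def toy_table(n, n_features=2, separable=True, seed=0):
    """Ordered binary table; separable=True puts the classes on either
    side of feature 0."""
    rng = np.random.default_rng(seed)
    labels = np.where(np.arange(n) % 2 == 0, "HC", "MDD")
    X = rng.normal(size=(n, n_features))
    if separable:
        X[:, 0] = np.where(labels == "MDD", 5.0, -5.0) + rng.normal(scale=0.1, size=n)
    cols = {f"f{i}": X[:, i] for i in range(n_features)}
    return pd.DataFrame({
        "subject_id": [f"s{i // 10}" for i in range(n)],
        "label": labels,
        "order_index": np.arange(n),
        **cols,
    })


class TestTimeOrderedSplit:
    def test_half_split_without_validation(self):
        t = toy_table(10)
        train, val, test = time_ordered_split(t, 0.5, 0.0)
        assert list(train["order_index"]) == list(range(5))
        assert len(val) == 0
        assert list(test["order_index"]) == list(range(5, 10))

    def test_paper_scale_floor_convention(self):
        t = toy_table(4950)
        train, val, test = time_ordered_split(t, 0.5, 0.3)
        assert (len(train), len(val), len(test)) == (1733, 742, 2475)
        # the three parts partition the table in order
        joined = pd.concat([train, val, test])
        assert list(joined["order_index"]) == list(range(4950))

    def test_split_is_deterministic(self):
        t = toy_table(100)
        a = time_ordered_split(t, 0.5, 0.3)
        b = time_ordered_split(t, 0.5, 0.3)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_invalid_fractions(self):
        t = toy_table(10)
        for args in [(0.0, 0.0), (1.0, 0.0), (0.5, 1.0)]:
            with pytest.raises(ValueError):
                time_ordered_split(t, *args)

    def test_unordered_table_rejected(self):
        t = toy_table(10).iloc[::-1].reset_index(drop=True)
        with pytest.raises(ValueError):
            time_ordered_split(t, 0.5, 0.0)


class TestChronologicalOrder:
    def test_subjects_appear_in_both_halves(self):
        # 3 subjects x 4 windows, subject-major
        t = toy_table(12)
        t["subject_id"] = np.repeat(["a", "b", "c"], 4)
        out = chronological_order(t)
        first, second = out.iloc[:6], out.iloc[6:]
        assert set(first["subject_id"]) == {"a", "b", "c"}
        assert set(second["subject_id"]) == {"a", "b", "c"}
        assert list(out["order_index"]) == list(range(12))

    def test_within_subject_time_order_preserved(self):
        t = toy_table(12)
        t["subject_id"] = np.repeat(["a", "b", "c"], 4)
        out = chronological_order(t)
        for s in "abc":
            rows = out[out["subject_id"] == s]
            assert list(rows["f0"]) == list(t[t["subject_id"] == s]["f0"])


class TestEvaluationReport:
    def test_hand_checked_confusion_matrix(self):
        rep = EvaluationReport(tp=40, fn=10, fp=5, tn=45)
        assert rep.accuracy == pytest.approx(85.0)
        assert rep.precision == pytest.approx(100 * 40 / 45)
        assert rep.recall == pytest.approx(80.0)
        assert rep.f1 == pytest.approx(100 * 2 * (40 / 45) * 0.8 / (40 / 45 + 0.8))

    def test_perfect_predictions(self):
        rep = EvaluationReport(tp=10, fn=0, fp=0, tn=10)
        assert (rep.accuracy, rep.precision, rep.recall, rep.f1) == (100.0,) * 4

    def test_all_positive_predictions_on_balanced_set(self):
        rep = EvaluationReport(tp=50, fn=0, fp=50, tn=0)
        assert rep.recall == 100.0
        assert rep.precision == 50.0
        assert rep.accuracy == 50.0

    def test_metric_identities_hold_for_random_confusions(self, rng):
        for _ in range(200):
            tp, fn, fp, tn = rng.integers(0, 100, size=4)
            if tp + fn + fp + tn == 0:
                continue
            rep = EvaluationReport(tp=int(tp), fn=int(fn), fp=int(fp), tn=int(tn))
            again = rep.recompute_metrics()
            for name in ("accuracy", "precision", "recall", "f1"):
                assert abs(getattr(rep, name) - again[name]) < 1e-12
            assert rep.n_rows == tp + fn + fp + tn

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            EvaluationReport(tp=-1, fn=0, fp=0, tn=0)


class TestFitAndEvaluate:
    def test_separable_toy_table_trains_to_100(self):
        t = toy_table(20)
        model = fit_classifier(t, ClassifierConfig(n_estimators=50))
        rep = evaluate(model, t)
        assert rep.accuracy == 100.0

    def test_uninformative_features_stay_near_chance(self):
        t = toy_table(200, separable=False)
        t[["f0", "f1"]] = 0.0  # identical features, alternating labels
        model = fit_classifier(t, ClassifierConfig(n_estimators=50))
        rep = evaluate(model, t)
        assert abs(rep.accuracy - 50.0) <= 10.0

    def test_single_class_training_rejected(self):
        t = toy_table(20)
        t["label"] = "HC"
        with pytest.raises(ValueError):
            fit_classifier(t)

    def test_column_mismatch_rejected(self):
        t = toy_table(20)
        model = fit_classifier(t, ClassifierConfig(n_estimators=10))
        with pytest.raises(ValueError):
            evaluate(model, t.rename(columns={"f0": "g0"}))

    def test_fixed_seed_reports_are_identical(self):
        t = toy_table(100, separable=False)
        cfg = ClassifierConfig(n_estimators=30, seed=7)
        a = evaluate(fit_classifier(t, cfg), t)
        b = evaluate(fit_classifier(t, cfg), t)
        assert a.confusion_matrix().tolist() == b.confusion_matrix().tolist()


class TestGridSearch:
    def test_single_cell_grid_returns_that_config(self):
        t = toy_table(40)
        best, grid = grid_search(t, t, leaves_grid=(10,), lr_grid=(0.1,),
                                 base_cfg=ClassifierConfig(n_estimators=20))
        assert best.num_leaves == 10 and best.learning_rate == 0.1
        assert grid.shape == (1, 1)

    def test_tie_breaks_prefer_fewer_leaves_then_larger_lr(self):
        t = toy_table(40)  # trivially separable: every cell scores 100%
        best, grid = grid_search(
            t, t, leaves_grid=(30, 10, 20), lr_grid=(0.05, 0.1),
            base_cfg=ClassifierConfig(n_estimators=20))
        assert (grid.to_numpy() == 100.0).all()
        assert best.num_leaves == 10
        assert best.learning_rate == 0.1

    def test_result_invariant_to_enumeration_order(self):
        t = toy_table(60, separable=False, seed=3)
        val = toy_table(30, separable=False, seed=4)
        base = ClassifierConfig(n_estimators=20)
        b1, _ = grid_search(t, val, (10, 31), (0.1, 0.01), base_cfg=base)
        b2, _ = grid_search(t, val, (31, 10), (0.01, 0.1), base_cfg=base)
        assert (b1.num_leaves, b1.learning_rate) == (b2.num_leaves, b2.learning_rate)

    def test_empty_grid_rejected(self):
        t = toy_table(20)
        with pytest.raises(ValueError):
            grid_search(t, t, (), (0.1,))


class TestCrossValidate:
    def test_contiguous_folds_of_equal_size(self):
        t = toy_table(100)
        report = cross_validate(t, ClassifierConfig(n_estimators=20), k=5)
        assert len(report.folds) == 5
        assert all(f.n_rows == 20 for f in report.folds)

    def test_perfect_separation_gives_zero_spread(self):
        t = toy_table(100)
        report = cross_validate(t, ClassifierConfig(n_estimators=30), k=5)
        assert all(f.accuracy == 100.0 for f in report.folds)
        assert report.sd["accuracy"] == 0.0
        assert report.mean["accuracy"] == 100.0

    def test_mean_lies_within_fold_range(self):
        t = toy_table(120, separable=False, seed=2)
        report = cross_validate(t, ClassifierConfig(n_estimators=20), k=4)
        accs = [f.accuracy for f in report.folds]
        assert min(accs) <= report.mean["accuracy"] <= max(accs)

    def test_shuffled_variant_is_seeded(self):
        t = toy_table(100, separable=False, seed=5)
        cfg = ClassifierConfig(n_estimators=20)
        a = cross_validate(t, cfg, k=5, seed=1, shuffle=True)
        b = cross_validate(t, cfg, k=5, seed=1, shuffle=True)
        assert [f.accuracy for f in a.folds] == [f.accuracy for f in b.folds]

    def test_invalid_fold_counts(self):
        t = toy_table(10)
        with pytest.raises(ValueError):
            cross_validate(t, k=1)
        with pytest.raises(ValueError):
            cross_validate(t, k=11)

    def test_cv_report_requires_two_folds(self):
        rep = EvaluationReport(tp=1, fn=0, fp=0, tn=1)
        with pytest.raises(ValueError):
            CVReport(folds=[rep])
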