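import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import rankdata

from ramanced import (
    CohortSpec,
    ConfigurationError,
    ConfusionMatrix,
    ModelConfig,
    SplitPlan,
    TrainSettings,
    confusion,
    generate_cohort,
    kfold_plan,
    make_split,
    metrics_from_confusion,
    roc_auc,
    run_comparison,
)


def fifty_nine_patients():
    return {f"ced{i:02d}": "CeD" for i in range(29)} | {
        f"ctl{i:02d}": "control" for i in range(30)
    }


class TestMakeSplit:
    def test_seven_three_split_partitions_59_patients(self):
        plan = make_split(fifty_nine_patients(), 0.3, seed=0)
        assert len(plan.train_patients) + len(plan.test_patients) == 59
        assert not set(plan.train_patients) & set(plan.test_patients)
        assert len(plan.test_patients) == 18  # ceil(0.3 * 59)

    def test_stratified_test_shares_within_one_patient(self):
        plan = make_split(fifty_nine_patients(), 0.3, seed=1)
        groups = fifty_nine_patients()
        n_ced_test = sum(1 for p in plan.test_patients if groups[p] == "CeD")
        expected = 0.3 * 29
        assert abs(n_ced_test - expected) <= 1

    def test_zero_test_fraction_warns_and_keeps_all_in_train(self):
        with pytest.warns(UserWarning, match="empty test set"):
            plan = make_split(fifty_nine_patients(), 0.0, seed=0)
        assert len(plan.train_patients) == 59 and plan.test_patients == ()

    def test_different_seeds_give_different_memberships(self):
        memberships = {
            make_split(fifty_nine_patients(), 0.3, seed=s).test_patients
            for s in range(20)
        }
        assert len(memberships) > 1

    def test_tiny_class_rejected_under_stratification(self):
        with pytest.raises(ConfigurationError, match="stratify"):
            make_split({"a": "CeD", "b": "control", "c": "control"}, 0.3)

    def test_floor_rounding_mode(self):
        plan = make_split(fifty_nine_patients(), 0.3, seed=0, rounding="floor")
        assert len(plan.test_patients) == 17


class TestKFold:
    def test_forty_patients_five_folds_of_eight(self):
        groups = dict(list(fifty_nine_patients().items())[:40])
        folds = kfold_plan(groups, k=5, seed=0)
        assert len(folds) == 5
        assert all(len(f) == 8 for f in folds)

    def test_leave_one_out_degenerate_case(self):
        groups = {f"p{i}": "CeD" if i % 2 else "control" for i in range(6)}
        folds = kfold_plan(groups, k=6, seed=0, stratified=False)
        assert all(len(f) == 1 for f in folds)

    def test_folds_partition_training_set(self):
        groups = fifty_nine_patients()
        folds = kfold_plan(groups, k=5, seed=3)
        flat = [p for f in folds for p in f]
        assert sorted(flat) == sorted(groups)
        assert max(len(f) for f in folds) - min(len(f) for f in folds) <= 1

    def test_k_larger_than_cohort_rejected(self):
        with pytest.raises(ConfigurationError, match="exceeds"):
            kfold_plan({"a": "CeD", "b": "control"}, k=5)


class TestConfusion:
    def test_perfect_prediction(self):
        cm = confusion([1, 1, 0, 0], [1, 1, 0, 0])
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (2, 2, 0, 0)

    def test_all_positive_predictions(self):
        cm = confusion([1, 0], [1, 1])
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (1, 1, 0, 0)

    def test_random_case_matches_brute_force_tally(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 200)
        p = rng.integers(0, 2, 200)
        cm = confusion(y, p)
        tally = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
        for yi, pi in zip(y, p):
            key = ("t" if yi == pi else "f") + ("p" if pi == 1 else "n")
            tally[key] += 1
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (
            tally["tp"], tally["tn"], tally["fp"], tally["fn"],
        )
        assert cm.total == 200

    def test_non_binary_labels_rejected(self):
        with pytest.raises(ConfigurationError, match="binary"):
            confusion([0, 1, 2], [0, 1, 1])


class TestMetrics:
    def test_symmetric_matrix_gives_point_nine_everywhere(self):
        rep = metrics_from_confusion(ConfusionMatrix(tp=9, tn=9, fp=1, fn=1))
        for value in (rep.accuracy, rep.sensitivity, rep.specificity, rep.precision):
            assert value == pytest.approx(0.9)

    def test_zero_false_negatives_gives_perfect_sensitivity(self):
        rep = metrics_from_confusion(ConfusionMatrix(tp=5, tn=3, fp=2, fn=0))
        assert rep.sensitivity == 1.0

    def test_literal_specificity_variant(self):
        cm = ConfusionMatrix(tp=3, tn=5, fp=2, fn=1)
        assert metrics_from_confusion(cm).specificity == pytest.approx(5 / 7)
        assert metrics_from_confusion(cm, "literal").specificity == pytest.approx(5 / 6)

    def test_undefined_metrics_reported_as_none(self):
        rep = metrics_from_confusion(ConfusionMatrix(tp=0, tn=4, fp=0, fn=0))
        assert rep.sensitivity is None and rep.precision is None
        assert rep.accuracy == 1.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ConfigurationError, match="empty"):
            metrics_from_confusion(ConfusionMatrix(0, 0, 0, 0))

    @given(
        tp=st.integers(0, 50), tn=st.integers(0, 50),
        fp=st.integers(0, 50), fn=st.integers(0, 50),
    )
    @settings(max_examples=200, derandomize=True)
    def test_accuracy_identity_holds_for_all_matrices(self, tp, tn, fp, fn):
        """accuracy == (sens*P + spec*N) / (P + N) whenever all terms exist."""
        if tp + tn + fp + fn == 0:
            return
        rep = metrics_from_confusion(ConfusionMatrix(tp, tn, fp, fn))
        p, n = tp + fn, tn + fp
        if rep.sensitivity is None or rep.specificity is None:
            return
        assert rep.accuracy == pytest.approx(
            (rep.sensitivity * p + rep.specificity * n) / (p + n)
        )


class TestROC:
    def test_perfect_separation(self):
        rep = roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert rep.auc == 1.0

    def test_all_tied_scores_give_chance(self):
        rep = roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])
        assert rep.auc == pytest.approx(0.5)
        np.testing.assert_allclose(rep.roc, [[0, 0], [1, 1]])

    def test_matches_mann_whitney_statistic(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            y = rng.integers(0, 2, 50)
            if y.min() == y.max():
                continue
            s = np.round(rng.normal(size=50), 1)  # induce ties
            ranks = rankdata(s)
            n_pos, n_neg = (y == 1).sum(), (y == 0).sum()
            u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2
            assert roc_auc(y, s).auc == pytest.approx(u / (n_pos * n_neg), abs=1e-10)

    def test_curve_monotone_and_anchored(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 40)
        s = rng.normal(size=40)
        roc = roc_auc(y, s).roc
        np.testing.assert_allclose(roc[0], [0, 0])
        np.testing.assert_allclose(roc[-1], [1, 1])
        assert np.all(np.diff(roc[:, 0]) >= 0) and np.all(np.diff(roc[:, 1]) >= 0)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 30)
        s = rng.normal(size=30)
        assert roc_auc(y, s).auc == pytest.approx(
            roc_auc(y, np.exp(3 * s)).auc, abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ConfigurationError, match="both classes"):
            roc_auc([1, 1, 1], [0.1, 0.5, 0.9])


class TestLeakageGuard:
    def test_overlapping_plan_rejected(self):
        with pytest.raises(ConfigurationError, match="both"):
            SplitPlan(("a", "b"), ("b", "c"))

    def test_bad_folds_rejected(self):
        with pytest.raises(ConfigurationError, match="partition"):
            SplitPlan(("a", "b", "c"), ("d",), folds=(("a",), ("b",)))


class TestRunComparison:
    def test_schema_and_sanity_floor_on_small_benchmark(self):
        spec = CohortSpec(
            n_ced=8, n_control=8, replicates_per_patient=1, seed=0,
            grid=__import__("ramanced").WavenumberGrid(500, 1524, 8),
        )
        cohort = generate_cohort(spec)
        settings_ = TrainSettings(epochs=30, validation_fraction=0.0, seed=0)
        configs = [
            ModelConfig(family=f, training=settings_)
            for f in ("svm", "knn", "cnn", "resnet", "drsn", "mcnn")
        ]
        table = run_comparison(
            cohort, configs, split_seed=0, run_cv=False, bootstrap=20
        )
        assert len(table) == 6
        metric_cols = [
            "auc_pct", "accuracy_pct", "sensitivity_pct",
            "specificity_pct", "precision_pct",
        ]
        assert all(c in table.columns for c in metric_cols)
        # far above the 0.5 - 3 sigma binomial floor for n_test = 5
        floor = 100 * (0.5 - 3 * np.sqrt(0.25 / 5))
        assert (table["accuracy_pct"] >= floor).all()
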