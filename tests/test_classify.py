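"""Tests for group statistics, learners, LOO evaluation and metrics."""

import numpy as np
import pandas as pd
import pytest

import lvscape as lv
from lvscape.classify import REPTree, RuleLearner, select_features


def make_table(x_a, x_b, labels=("A", "B"), n_noise=3, seed=0):
    """Two-group table: one informative feature plus noise columns."""
    rng = np.random.default_rng(seed)
    n = len(x_a) + len(x_b)
    frame = pd.DataFrame({"signal": np.concatenate([x_a, x_b])})
    for j in range(n_noise):
        frame[f"noise{j}"] = rng.normal(size=n)
    frame["label"] = [labels[0]] * len(x_a) + [labels[1]] * len(x_b)
    return frame


class TestGroupCompare:
    def test_identical_groups_give_maximal_p(self):
        x = np.arange(10, dtype=float)
        table = make_table(x, x)
        p = lv.group_compare(table, table["label"], ("A", "B"), features=["signal"])
        assert p["signal"] > 0.99

    def test_strong_shift_is_detected(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 20)
        b = rng.normal(30, 1, 20)
        table = make_table(a, b)
        p = lv.group_compare(table, table["label"], ("A", "B"), features=["signal"])
        assert p["signal"] < 1e-4

    def test_type_one_error_rate_under_null(self):
        """Rejection rate at alpha = 0.05 stays inside the binomial 95% band."""
        rng = np.random.default_rng(7)
        n_rep, n_per = 400, 12
        rejections = 0
        for _ in range(n_rep):
            x = rng.normal(size=n_per)
            y = rng.normal(size=n_per)
            table = make_table(x, y, n_noise=0)
            p = lv.group_compare(
                table, table["label"], ("A", "B"), features=["signal"]
            )
            rejections += p["signal"] < 0.05
        rate = rejections / n_rep
        band = 1.96 * np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) < band + 1e-9

    def test_small_group_rejected(self):
        table = make_table(np.array([1.0]), np.arange(5, dtype=float))
        with pytest.raises(ValueError):
            lv.group_compare(table, table["label"], ("A", "B"))

    def test_signed_rank_variant_on_paired_data(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 15)
        b = a + rng.normal(2, 0.2, 15)
        table = make_table(a, b, n_noise=0)
        p = lv.group_compare(
            table, table["label"], ("A", "B"), features=["signal"], method="signedrank"
        )
        assert p["signal"] < 1e-3


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha, m, expected", [(0.05, 9, 0.05 / 9), (0.05, 1, 0.05), (0.10, 2, 0.05)]
    )
    def test_threshold(self, alpha, m, expected):
        assert lv.bonferroni_threshold(alpha, m) == pytest.approx(expected)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            lv.bonferroni_threshold(1.5, 3)
        with pytest.raises(ValueError):
            lv.bonferroni_threshold(0.05, 0)


class TestFeatureSelection:
    def test_predictive_feature_ranks_above_noise(self):
        rng = np.random.default_rng(0)
        y = np.repeat(["A", "B"], 30)
        X = rng.normal(size=(60, 6))
        X[:, 2] += (y == "A") * 5.0
        for method in ("correlation", "infogain"):
            sel = select_features(X, y, method=method, k=1, seed=0)
            assert list(sel) == [2]


class TestLearners:
    @pytest.mark.parametrize("cls", [RuleLearner, REPTree])
    def test_separable_problem_is_learned(self, cls):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 1, (30, 3)), rng.normal(8, 1, (30, 3))])
        y = np.array(["neg"] * 30 + ["pos"] * 30)
        model = cls(seed=0).fit(X, y)
        assert np.mean(model.predict(X) == y) == 1.0
        proba = model.predict_proba(X)
        assert proba.shape == (60, 2)
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_rule_learner_targets_minority_class(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 1, (40, 2)), rng.normal(6, 1, (10, 2))])
        y = np.array(["big"] * 40 + ["small"] * 10)
        model = RuleLearner(seed=0).fit(X, y)
        assert model.pos_class_ == "small"
        assert np.mean(model.predict(X) == y) >= 0.9


class TestLooClassify:
    def test_perfectly_separated_clusters(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 20)
        b = rng.normal(20, 1, 20)
        table = make_table(a, b, seed=1)
        for learner in ("rule", "tree"):
            report = lv.loo_classify(table, learner=learner, n_features=2, seed=0)
            assert report.metrics["accuracy"] == 1.0
            assert np.all(np.diag(report.confusion) == [20, 20])

    def test_permuted_labels_score_at_chance(self):
        """Guards against held-out leakage through feature selection."""
        rng = np.random.default_rng(11)
        table = pd.DataFrame(rng.normal(size=(60, 5)), columns=list("abcde"))
        table["label"] = rng.permutation(np.repeat(["A", "B"], 30))
        report = lv.loo_classify(table, learner="tree", n_features=3, seed=0)
        acc = report.metrics["accuracy"]
        band = 1.96 * np.sqrt(0.25 / 60)
        assert abs(acc - 0.5) < band + 0.05

    def test_selection_frequency_separates_signal_from_noise(self):
        rng = np.random.default_rng(9)
        y = np.repeat(["A", "B"], 20)
        table = pd.DataFrame({"pure_noise": rng.normal(size=40)})
        for j in range(3):
            table[f"weak{j}"] = rng.normal(size=40) + (y == "A") * 1.0
        table["predictive"] = rng.normal(size=40) + (y == "A") * 10.0
        table["label"] = y
        report = lv.loo_classify(table, learner="tree", n_features=2, seed=0)
        freq = report.feature_frequency
        assert freq["predictive"] == 100.0
        assert freq["pure_noise"] < freq["predictive"] / 2

    def test_unknown_learner_rejected(self):
        table = make_table(np.zeros(3), np.ones(3))
        with pytest.raises(ValueError):
            lv.loo_classify(table, learner="forest")


class TestMetricsFromConfusion:
    def test_healthy_versus_patients_printed_row(self):
        """Reconstructed two-class table: 42/49 correct vs 98/98 correct."""
        cm = lv.confusion_from_rates([0.857, 1.000], [49, 98])
        assert cm.tolist() == [[42, 7], [0, 98]]
        m = lv.metrics_from_confusion(cm, class_names=["HC", "DOC"])
        hc = m["per_class"]["HC"]
        assert hc["tp_rate"] == pytest.approx(0.857, abs=5e-4)
        assert hc["fp_rate"] == pytest.approx(0.000, abs=5e-4)
        assert hc["precision"] == pytest.approx(1.000, abs=5e-4)
        assert hc["f_measure"] == pytest.approx(0.923, abs=5e-4)
        assert hc["mcc"] == pytest.approx(0.894, abs=5e-4)
        doc = m["per_class"]["DOC"]
        assert doc["tp_rate"] == pytest.approx(1.000, abs=5e-4)
        assert doc["precision"] == pytest.approx(0.933, abs=5e-4)
        assert m["weighted"]["precision"] == pytest.approx(0.956, abs=5e-4)

    def test_patient_subgroup_printed_row(self):
        cm = lv.confusion_from_rates([0.921, 0.771], [63, 35])
        assert cm.tolist() == [[58, 5], [8, 27]]
        m = lv.metrics_from_confusion(cm, class_names=["MCS", "UWS"])
        mcs = m["per_class"]["MCS"]
        assert mcs["tp_rate"] == pytest.approx(0.921, abs=5e-4)
        assert mcs["fp_rate"] == pytest.approx(0.229, abs=5e-4)
        assert mcs["precision"] == pytest.approx(0.879, abs=5e-4)
        assert mcs["f_measure"] == pytest.approx(0.899, abs=5e-4)
        assert mcs["mcc"] == pytest.approx(0.707, abs=5e-4)
        uws = m["per_class"]["UWS"]
        assert uws["precision"] == pytest.approx(0.844, abs=5e-4)
        assert uws["tp_rate"] == pytest.approx(0.771, abs=5e-4)
        assert m["weighted"]["precision"] == pytest.approx(0.866, abs=5e-4)

    def test_perfect_diagonal(self):
        m = lv.metrics_from_confusion(np.diag([10, 15]), class_names=["A", "B"])
        for cls in ("A", "B"):
            row = m["per_class"][cls]
            assert row["tp_rate"] == 1.0 and row["fp_rate"] == 0.0
            assert row["mcc"] == 1.0
        assert m["accuracy"] == 1.0

    def test_zero_division_is_flagged_not_raised(self):
        # no predictions at all for class B
        m = lv.metrics_from_confusion(np.array([[5, 0], [3, 0]]), class_names=["A", "B"])
        assert m["per_class"]["B"]["precision"] == 0.0
        assert ("B", "precision") in m["zero_division_flags"]

    def test_roc_and_prc_from_scores(self):
        y = np.array(["A", "A", "B", "B"])
        scores = np.array([[0.9, 0.1], [0.8, 0.2], [0.2, 0.8], [0.1, 0.9]])
        cm = np.array([[2, 0], [0, 2]])
        m = lv.metrics_from_confusion(cm, ["A", "B"], scores=scores, y_true=y)
        assert m["per_class"]["A"]["roc_area"] == 1.0
        assert m["per_class"]["B"]["prc_area"] == pytest.approx(1.0)
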