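"""Classifiers, stratified folds, confusion metrics, and the CV harness."""

from dataclasses import replace

import numpy as np
import pytest

import nmrlbp as nl
from nmrlbp.classify import (
    ConfusionCounts,
    dt_predict,
    dt_train,
    knn_predict,
    knn_train,
    svm_predict,
    svm_train,
)

GEO, NON = nl.GEO_AUTHENTIC, nl.NON_AUTHENTIC


class TestDistance:
    def test_pythagorean_triple(self):
        assert nl.euclidean_distance((0, 0), (3, 4)) == 5.0

    def test_identity(self):
        assert nl.euclidean_distance((1.5, -2.0), (1.5, -2.0)) == 0.0

    def test_three_dims(self):
        assert nl.euclidean_distance((1, 2, 3), (4, 6, 3)) == 5.0

    def test_length_mismatch(self):
        with pytest.raises(nl.ParameterError):
            nl.euclidean_distance((1, 2), (1, 2, 3))


class TestKnn:
    def test_k1_memorizes_training_points(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([GEO, GEO, NON, NON])
        model = knn_train(X, y, nl.ClassifierSpec(kind="knn", knn_k=1))
        assert list(knn_predict(model, X)) == list(y)

    def test_majority_beats_proximity(self):
        # two class-A neighbors at distance 1 outvote one class-B at 0.5
        X = np.array([[1.0], [-1.0], [0.5]])
        y = np.array(["A", "A", "B"])
        model = knn_train(X, y, nl.ClassifierSpec(kind="knn", knn_k=3))
        assert knn_predict(model, [[0.0]])[0] == "A"

    def test_even_k_tie_broken_by_nearer_class(self):
        X = np.array([[-2.0], [-0.5], [0.5], [2.0]])
        y = np.array(["A", "B", "B", "A"])
        model = knn_train(X, y, nl.ClassifierSpec(kind="knn", knn_k=4))
        # 2 votes each; B's neighbors are nearer in summed distance
        assert knn_predict(model, [[0.0]])[0] == "B"

    def test_single_class_training_rejected(self):
        with pytest.raises(nl.ModelError):
            knn_train(np.zeros((3, 2)), np.array(["A", "A", "A"]))

    def test_empty_training_rejected(self):
        with pytest.raises(nl.ModelError):
            knn_train(np.zeros((0, 2)), np.array([]))


class TestDecisionTree:
    def test_margin_separated_1d(self):
        X = np.array([[-3.0], [-2.0], [-1.0], [1.0], [2.0], [3.0]])
        y = np.array([NON] * 3 + [GEO] * 3)
        model = dt_train(X, y)
        assert list(dt_predict(model, X)) == list(y)

    def test_single_class_constant_predictor_when_allowed(self):
        X = np.array([[0.0], [1.0]])
        y = np.array(["A", "A"])
        model = dt_train(X, y, require_both_classes=False)
        assert list(dt_predict(model, [[5.0]])) == ["A"]

    def test_xor_needs_depth_two(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        y = np.array(["A", "B", "B", "A"])
        model = dt_train(X, y, nl.ClassifierSpec(kind="dt", dt_max_depth=2))
        assert list(dt_predict(model, X)) == list(y)
        assert model.get_depth() == 2


class TestSvm:
    def test_symmetric_separable_max_margin(self):
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = np.array([-1, -1, 1, 1])
        model = svm_train(X, y, nl.ClassifierSpec(kind="svm", svm_c=1e6))
        w, b = model.w_[0], model.b_
        assert w == pytest.approx(1.0, abs=1e-3)
        assert b == pytest.approx(0.0, abs=1e-3)
        # margin points at +-1: smallest functional margin is exactly 1
        assert min(y * (w * X.ravel() + b)) == pytest.approx(1.0, abs=1e-3)

    def test_margin_property_on_separable_data(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(-3, 0.3, (20, 2)), rng.normal(3, 0.3, (20, 2))])
        y = np.array([-1] * 20 + [1] * 20)
        model = svm_train(X, y, nl.ClassifierSpec(kind="svm", svm_c=1e6))
        functional = y * (X @ model.w_ + model.b_)
        assert np.all(functional >= 1 - 1e-6)
        assert np.mean(svm_predict(model, X) == y) == 1.0

    def test_xor_not_linearly_separable(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        y = np.array([-1, 1, 1, -1])
        model = svm_train(X, y, nl.ClassifierSpec(kind="svm", svm_c=100.0))
        assert np.mean(svm_predict(model, X) == y) <= 0.75

    def test_single_class_rejected(self):
        with pytest.raises(nl.ModelError):
            svm_train(np.zeros((3, 2)), np.array([1, 1, 1]))


class TestStratifiedKFold:
    def test_140_balanced_gives_28_per_fold(self):
        labels = np.array([GEO] * 70 + [NON] * 70)
        folds = nl.stratified_kfold(labels, 5, seed=0)
        for f in range(5):
            te = folds.test_indices(f)
            assert te.size == 28
            assert folds.train_indices(f).size == 112
            assert np.sum(labels[te] == GEO) == 14

    def test_disjoint_cover(self):
        labels = np.array([GEO] * 11 + [NON] * 9)
        folds = nl.stratified_kfold(labels, 4, seed=1)
        all_idx = np.concatenate([folds.test_indices(f) for f in range(4)])
        assert np.array_equal(np.sort(all_idx), np.arange(20))

    def test_round_robin_fold_sizes(self):
        labels = np.array(["A"] * 5 + ["B"] * 5)
        folds = nl.stratified_kfold(labels, 3, seed=2)
        sizes = sorted((folds.test_indices(f).size for f in range(3)), reverse=True)
        assert sizes == [4, 3, 3]

    def test_class_smaller_than_k_rejected(self):
        with pytest.raises(nl.ParameterError):
            nl.stratified_kfold(np.array(["A"] * 2 + ["B"] * 10), 3)

    def test_balanced_folds_within_one_sample(self):
        rng = np.random.default_rng(3)
        labels = np.array([GEO, NON])[rng.integers(0, 2, 101)]
        k = 5
        folds = nl.stratified_kfold(labels, k, seed=4)
        for c in (GEO, NON):
            per_fold = [np.sum(labels[folds.test_indices(f)] == c) for f in range(k)]
            assert max(per_fold) - min(per_fold) <= 1


class TestConfusionAndMetrics:
    def test_perfect_prediction(self):
        y = np.array([GEO] * 14 + [NON] * 14)
        cc = nl.confusion(y, y)
        assert (cc.tp, cc.tn, cc.fp, cc.fn) == (14, 14, 0, 0)
        m = nl.compute_metrics(cc)
        assert (m.acc, m.sen, m.f1) == (100.0, 100.0, 1.0)

    def test_all_predicted_positive(self):
        y_true = np.array([GEO, GEO, NON, NON])
        y_pred = np.array([GEO] * 4)
        cc = nl.confusion(y_true, y_pred)
        assert cc.fn == 0 and cc.tn == 0

    def test_mixed_pairs(self):
        y_true = np.array([GEO, GEO, NON, NON])
        y_pred = np.array([GEO, NON, GEO, NON])
        cc = nl.confusion(y_true, y_pred)
        assert (cc.tp, cc.fn, cc.fp, cc.tn) == (1, 1, 1, 1)

    def test_two_decimal_rounding_case(self):
        m = nl.compute_metrics(ConfusionCounts(tp=69, fn=1, tn=67, fp=3))
        assert round(m.acc, 2) == 97.14
        assert round(m.sen, 2) == 98.57

    def test_zero_over_zero_defined_as_zero(self):
        m = nl.compute_metrics(ConfusionCounts(tp=0, fn=5, tn=5, fp=0))
        assert m.sen == 0.0
        assert m.f1 == 0.0

    def test_acc_agrees_with_mean_zero_one_loss(self):
        rng = np.random.default_rng(5)
        y_true = np.array([GEO, NON])[rng.integers(0, 2, 200)]
        y_pred = np.array([GEO, NON])[rng.integers(0, 2, 200)]
        cc = nl.confusion(y_true, y_pred)
        assert nl.compute_metrics(cc).acc == np.mean(y_true == y_pred) * 100.0

    def test_unknown_positive_label_rejected(self):
        with pytest.raises(nl.ParameterError):
            nl.confusion(np.array(["A", "B"]), np.array(["A", "B"]), positive_label="C")


class TestHarness:
    def test_pooled_counts_are_fold_sums(self, small_dataset):
        rep = nl.run_experiment(small_dataset, "exp2_preprocessed",
                                nl.ClassifierSpec(kind="knn"), k=4, seed=0)
        total = rep.fold_counts[0]
        for cc in rep.fold_counts[1:]:
            total = total + cc
        assert total == rep.pooled_counts
        assert rep.pooled_counts.total == len(small_dataset)

    def test_knn_k1_self_consistency(self, exp3_features, default_labels):
        model = knn_train(exp3_features, default_labels,
                          nl.ClassifierSpec(kind="knn", knn_k=1))
        cc = nl.confusion(default_labels, knn_predict(model, exp3_features))
        assert nl.compute_metrics(cc).acc == 100.0

    def test_regime_accuracy_ordering(self, default_dataset, exp3_features, default_labels):
        spec = nl.ClassifierSpec(kind="svm")
        acc = {}
        for regime in ("exp1_raw", "exp2_preprocessed"):
            acc[regime] = nl.run_experiment(default_dataset, regime, spec, seed=1).pooled_metrics.acc
        acc["exp3_lbp"] = nl.cross_validate(
            exp3_features, default_labels, spec, seed=1, regime="exp3_lbp"
        ).pooled_metrics.acc
        assert acc["exp3_lbp"] >= acc["exp2_preprocessed"] >= acc["exp1_raw"]

    def test_unknown_regime_rejected(self, small_dataset):
        with pytest.raises(nl.ParameterError, match="regime"):
            nl.run_experiment(small_dataset, "exp9")

    def test_report_serialization_schema(self, small_dataset):
        rep = nl.run_experiment(small_dataset, "exp1_raw", nl.ClassifierSpec(kind="dt"), k=4)
        d = rep.to_dict()
        assert {"regime", "classifier", "folds", "pooled", "fold_mean",
                "train_predict_seconds"} <= set(d)
        row = rep.summary_row()
        assert {"accuracy_pct", "sensitivity_pct", "f1_score"} <= set(row)

    def test_null_data_gives_chance_level_accuracy(self):
        accs = []
        for s in range(20):
            params = replace(nl.default_synth_params(), n_geo=10, n_non=10,
                             n_points=512, class_ratio=1.0, seed=3000 + s)
            ds = nl.generate_dataset(params)
            rep = nl.run_experiment(ds, "exp1_raw", nl.ClassifierSpec(kind="knn"), seed=s)
            accs.append(rep.pooled_metrics.acc)
        assert 35.0 <= np.mean(accs) <= 65.0
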