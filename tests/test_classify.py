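"""Holdout / cross-validation / random-forest protocol and metrics."""

import numpy as np
import pandas as pd
import pytest

from vibrotrace.classify import (LABELS, EvaluationReport, RFConfig, crossval,
                                 evaluate, holdout_split,
                                 metrics_from_confusion, run_protocol,
                                 train_rf)
from vibrotrace.descriptors import FEATURE_COLUMNS

from ._oracles import mann_whitney_auc


def make_table(n_per_class, separation=0.0, seed=0, source="s"):
    """Balanced two-class table with Gaussian features."""
    rng = np.random.default_rng(seed)
    rows = []
    for ci, label in enumerate(LABELS):
        X = rng.normal(size=(n_per_class, len(FEATURE_COLUMNS)))
        X += ci * separation
        for x in X:
            rows.append({**dict(zip(FEATURE_COLUMNS, x)),
                         "group_label": label, "valid": True,
                         "source_id": f"{source}-{label}"})
    return pd.DataFrame(rows)


class TestHoldoutSplit:
    def test_stratified_counts(self):
        table = make_table(50)
        train, test = holdout_split(table, 0.2, seed=1)
        assert len(test) == 20
        assert (test["group_label"].value_counts() == 10).all()

    def test_deterministic_and_partition(self):
        table = make_table(40).reset_index()
        a_train, a_test = holdout_split(table, 0.2, seed=5)
        b_train, b_test = holdout_split(table, 0.2, seed=5)
        assert a_test["index"].tolist() == b_test["index"].tolist()
        ids = set(a_train["index"]) | set(a_test["index"])
        assert ids == set(table["index"])
        assert not set(a_train["index"]) & set(a_test["index"])

    def test_tiny_class_rejected(self):
        table = make_table(30)
        table = pd.concat([table[table.group_label == LABELS[0]],
                           table[table.group_label == LABELS[1]].head(1)])
        with pytest.raises(ValueError):
            holdout_split(table, 0.2)


class TestCrossval:
    def test_separable_clusters_are_perfect(self):
        cv = crossval(make_table(50, separation=10.0), k=5)
        assert cv["mean"] == 1.0 and cv["sd"] == 0.0

    def test_null_labels_near_chance(self):
        # permuted labels: accuracy concentrates at 1/2 for n = 2000
        table = make_table(1000, separation=0.0, seed=3)
        cv = crossval(table, k=5)
        assert 0.45 <= cv["mean"] <= 0.55

    def test_fold_class_ratio_within_one_sample(self):
        from sklearn.model_selection import StratifiedKFold
        table = make_table(51)
        y = table["group_label"].to_numpy()
        for _, va in StratifiedKFold(5, shuffle=True,
                                     random_state=42).split(table, y):
            counts = pd.Series(y[va]).value_counts()
            assert abs(counts.iloc[0] - counts.iloc[1]) <= 1

    def test_class_smaller_than_k_rejected(self):
        with pytest.raises(ValueError):
            crossval(make_table(3), k=5)

    def test_ci_forms(self):
        cv = crossval(make_table(30, separation=1.0), k=5)
        lo, hi = cv["ci95_normal"]
        assert lo == pytest.approx(cv["mean"] - 1.96 * cv["sd"] / np.sqrt(5))
        lo2, hi2 = cv["ci95_sd"]
        assert hi2 == pytest.approx(cv["mean"] + cv["sd"])


class TestTrainRF:
    def test_separable_training_accuracy_one(self):
        table = make_table(30, separation=10.0)
        model = train_rf(table)
        X = table[list(FEATURE_COLUMNS)].to_numpy()
        assert np.mean(model.predict(X) == table["group_label"]) == 1.0

    def test_same_seed_reproduces_probabilities(self):
        table = make_table(40, separation=0.5)
        X = table[list(FEATURE_COLUMNS)].to_numpy()
        p1 = train_rf(table).predict_proba(X)
        p2 = train_rf(table).predict_proba(X)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_rejected(self):
        table = make_table(20)
        with pytest.raises(ValueError):
            train_rf(table[table.group_label == LABELS[0]])

    def test_config_defaults(self):
        cfg = RFConfig()
        assert (cfg.n_estimators, cfg.random_state) == (100, 42)
        assert cfg.criterion == "gini" and cfg.max_features == "sqrt"
        assert cfg.max_depth is None and cfg.bootstrap
        assert (cfg.min_samples_split, cfg.min_samples_leaf) == (2, 1)


class TestMetricsFromConfusion:
    def test_published_confusion_reproduces_published_metrics(self):
        m = metrics_from_confusion([[645, 108], [122, 637]])
        assert round(m["overall_accuracy"], 2) == 0.85
        ctrl, alz = m["per_class"]["Control"], m["per_class"]["Alzheimer"]
        assert round(ctrl["recall"], 2) == 0.86
        assert round(alz["recall"], 2) == 0.84
        assert round(ctrl["f1"], 2) == 0.85
        assert round(alz["f1"], 2) == 0.85
        assert round(ctrl["precision"], 2) == 0.84
        assert round(alz["precision"], 2) == 0.86
        assert round(ctrl["specificity"], 2) == 0.84
        assert round(alz["specificity"], 2) == 0.86

    def test_identity_confusion(self):
        m = metrics_from_confusion([[10, 0], [0, 15]])
        assert m["overall_accuracy"] == 1.0
        for stats in m["per_class"].values():
            assert stats["recall"] == 1.0 and stats["f1"] == 1.0

    def test_self_consistency(self, rng):
        cm = rng.integers(0, 500, size=(2, 2))
        m = metrics_from_confusion(cm)
        tp, fn = cm[0, 0], cm[0, 1]
        assert m["per_class"]["Control"]["recall"] == pytest.approx(
            tp / (tp + fn))

    def test_bad_shapes_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_confusion([[1, 2, 3], [4, 5, 6]])
        with pytest.raises(ValueError):
            metrics_from_confusion([[-1, 2], [3, 4]])


class TestEvaluate:
    def test_perfect_predictions(self):
        table = make_table(40, separation=10.0)
        model = train_rf(table)
        rep = evaluate(model, table)
        assert rep.overall_accuracy == 1.0
        assert rep.auc == 1.0
        assert np.trace(rep.confusion) == len(table)

    def test_uninformative_scores_give_half_auc(self):
        from sklearn.metrics import roc_curve, auc as sk_auc
        y = np.array([LABELS[1]] * 50 + [LABELS[0]] * 50)
        scores = np.full(100, 0.5)
        fpr, tpr, _ = roc_curve(y, scores, pos_label=LABELS[1])
        assert sk_auc(fpr, tpr) == 0.5

    def test_auc_matches_rank_oracle_and_monotone_invariance(self):
        table = make_table(60, separation=0.8, seed=9)
        model = train_rf(table)
        test = make_table(40, separation=0.8, seed=10)
        rep = evaluate(model, test)
        X = test[list(FEATURE_COLUMNS)].to_numpy()
        pos = list(model.classes_).index("Alzheimer")
        scores = model.predict_proba(X)[:, pos]
        y = test["group_label"].to_numpy()
        oracle = mann_whitney_auc(scores[y == "Alzheimer"],
                                  scores[y == "Control"])
        assert rep.auc == pytest.approx(oracle, abs=1e-9)
        # strictly monotone transform of the scores leaves AUC unchanged
        assert mann_whitney_auc(np.exp(3 * scores[y == "Alzheimer"]),
                                np.exp(3 * scores[y == "Control"])) == \
            pytest.approx(oracle, abs=1e-9)

    def test_metrics_recomputable_from_confusion(self):
        table = make_table(60, separation=0.6, seed=2)
        model = train_rf(table)
        rep = evaluate(model, make_table(40, separation=0.6, seed=4))
        again = metrics_from_confusion(rep.confusion)
        assert again["overall_accuracy"] == pytest.approx(
            rep.overall_accuracy)
        for lbl in LABELS:
            for key in ("precision", "recall", "f1", "specificity"):
                assert again["per_class"][lbl][key] == pytest.approx(
                    rep.per_class[lbl][key])


class TestRunProtocol:
    def _groups(self, n, sep, seed):
        rng = np.random.default_rng(seed)
        out = {}
        for ci, label in enumerate(LABELS):
            X = rng.normal(size=(n, len(FEATURE_COLUMNS))) + ci * sep
            out[label] = pd.DataFrame(X, columns=FEATURE_COLUMNS).assign(
                valid=True, source_id=f"run-{label}")
        return out

    def test_report_schema_complete(self):
        rep = run_protocol(self._groups(60, 1.0, 0))
        d = rep.to_dict()
        for key in ("confusion", "per_class", "overall_accuracy", "auc",
                    "cv_mean", "cv_sd", "cv_ci95_normal", "cv_ci95_sd",
                    "roc"):
            assert key in d and d[key] is not None

    def test_null_groups_near_chance(self):
        rep = run_protocol(self._groups(1000, 0.0, 1))
        assert 0.45 <= rep.overall_accuracy <= 0.57

    def test_separated_groups_high_auc(self):
        rep = run_protocol(self._groups(300, 1.5, 2))
        assert rep.auc >= 0.8

    def test_paper_mode_logs_leakage_warning(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="vibrotrace.classify"):
            run_protocol(self._groups(30, 1.0, 3))
        assert any("pseudo-replication" in r.message for r in caplog.records)

    def test_needs_exactly_two_groups(self):
        groups = self._groups(20, 1.0, 4)
        groups.pop(LABELS[0])
        with pytest.raises(ValueError):
            run_protocol(groups)
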