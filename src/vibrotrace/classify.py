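"""Random-forest classification of frame descriptors with the holdout +
stratified 5-fold cross-validation protocol.

Frames carry one of two labels (``Control`` / ``Alzheimer``). The default
protocol mirrors a frame-level 80/20 stratified holdout with stratified
5-fold CV on the training portion, a 100-tree gini random forest
(random_state 42, sqrt feature sampling), and evaluation on the untouched
test split: confusion matrix, per-class precision / recall / F1 /
specificity, overall accuracy, ROC curve and AUC from ensemble vote
fractions.

Frame-level splitting treats correlated frames from one recording as
independent samples (pseudo-replication). A ``grouped`` mode that keeps
all frames of one source on one side of the split is provided; the
default ``paper`` mode logs a leakage warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import confusion_matrix, roc_curve
from sklearn.model_selection import (GroupShuffleSplit, StratifiedKFold,
                                     train_test_split)

from .descriptors import FEATURE_COLUMNS

__all__ = [
    "LABELS",
    "POSITIVE_LABEL",
    "RFConfig",
    "EvaluationReport",
    "holdout_split",
    "crossval",
    "train_rf",
    "evaluate",
    "metrics_from_confusion",
    "run_protocol",
]

logger = logging.getLogger(__name__)

#: Class order used everywhere: index 0 = Control (negative),
#: index 1 = Alzheimer (positive class for ROC).
LABELS = ("Control", "Alzheimer")
POSITIVE_LABEL = "Alzheimer"


@dataclass(frozen=True)
class RFConfig:
    """Random-forest hyperparameters (library defaults of the protocol)."""

    n_estimators: int = 100
    random_state: int = 42
    max_depth: int | None = None
    criterion: str = "gini"
    min_samples_split: int = 2
    min_samples_leaf: int = 1
    bootstrap: bool = True
    max_features: str = "sqrt"

    def make(self) -> RandomForestClassifier:
        return RandomForestClassifier(**asdict(self))


@dataclass
class EvaluationReport:
    """Test-set evaluation plus (optionally) the CV summary."""

    confusion: np.ndarray            # rows = true class, cols = predicted
    per_class: dict                  # label -> {precision, recall, f1, specificity}
    overall_accuracy: float
    roc: tuple | None = None         # (fpr, tpr, thresholds)
    auc: float | None = None
    cv_mean: float | None = None
    cv_sd: float | None = None
    cv_ci95_normal: tuple | None = None   # mean +/- 1.96 sd / sqrt(k)
    cv_ci95_sd: tuple | None = None       # mean +/- sd

    def to_dict(self) -> dict:
        d = {
            "confusion": np.asarray(self.confusion).tolist(),
            "labels": list(LABELS),
            "per_class": self.per_class,
            "overall_accuracy": self.overall_accuracy,
            "auc": self.auc,
            "cv_mean": self.cv_mean,
            "cv_sd": self.cv_sd,
            "cv_ci95_normal": list(self.cv_ci95_normal) if self.cv_ci95_normal else None,
            "cv_ci95_sd": list(self.cv_ci95_sd) if self.cv_ci95_sd else None,
        }
        if self.roc is not None:
            d["roc"] = {"fpr": self.roc[0].tolist(), "tpr": self.roc[1].tolist()}
        return d


def _check_table(table: pd.DataFrame, features=FEATURE_COLUMNS) -> None:
    missing = [c for c in (*features, "group_label") if c not in table.columns]
    if missing:
        raise ValueError(f"feature table lacks columns: {missing}")


def _xy(table: pd.DataFrame, features=FEATURE_COLUMNS):
    X = table.loc[:, list(features)].to_numpy(dtype=float)
    y = table["group_label"].to_numpy()
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains missing values; drop "
                         "invalid frames first")
    return X, y


def holdout_split(table: pd.DataFrame, test_fraction: float = 0.20,
                  stratified: bool = True, seed: int = 42):
    """Disjoint, exhaustive train/test split of a feature table."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    _check_table(table)
    strat = table["group_label"] if stratified else None
    if stratified and table["group_label"].value_counts().min() < 2:
        raise ValueError("stratified split needs >= 2 rows per class")
    train, test = train_test_split(table, test_size=test_fraction,
                                   stratify=strat, random_state=seed)
    return train, test


def crossval(train: pd.DataFrame, k: int = 5, config: RFConfig = RFConfig(),
             seed: int = 42, features=FEATURE_COLUMNS) -> dict:
    """Stratified k-fold CV accuracy on the training table.

    Returns mean, sd (population), per-fold accuracies, and two interval
    forms: mean +/- 1.96 sd / sqrt(k) (normal-theory) and mean +/- sd.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    _check_table(train, features)
    X, y = _xy(train, features)
    counts = pd.Series(y).value_counts()
    if counts.min() < k:
        raise ValueError(f"smallest class has {counts.min()} rows < k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs = []
    for tr, va in skf.split(X, y):
        model = config.make().fit(X[tr], y[tr])
        accs.append(float(np.mean(model.predict(X[va]) == y[va])))
    accs = np.array(accs)
    mean, sd = float(accs.mean()), float(accs.std())
    half = 1.96 * sd / np.sqrt(k)
    return {
        "fold_accuracies": accs.tolist(),
        "mean": mean,
        "sd": sd,
        "ci95_normal": (mean - half, mean + half),
        "ci95_sd": (mean - sd, mean + sd),
    }


def train_rf(train: pd.DataFrame, config: RFConfig = RFConfig(),
             features=FEATURE_COLUMNS) -> RandomForestClassifier:
    """Fit the random forest on a training table."""
    _check_table(train, features)
    X, y = _xy(train, features)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain two classes")
    return config.make().fit(X, y)


def metrics_from_confusion(cm) -> dict:
    """Standard binary metrics from a 2x2 confusion matrix.

    ``cm[i, j]`` counts true class i predicted as class j, classes
    ordered as ``LABELS`` (Control, Alzheimer). Per-class precision is
    also reported under the alias ``accuracy`` as some summaries label
    the per-class precision column that way.
    """
    cm = np.asarray(cm, dtype=float)
    if cm.shape != (2, 2) or (cm < 0).any():
        raise ValueError("confusion matrix must be 2x2 with counts >= 0")
    per_class = {}
    for i, lbl in enumerate(LABELS):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = cm.sum() - tp - fn - fp
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = (2 * precision * recall / (precision + recall)
              if precision + recall else 0.0)
        specificity = tn / (tn + fp) if tn + fp else 0.0
        per_class[lbl] = {
            "precision": precision,
            "accuracy": precision,  # per-class alias
            "recall": recall,
            "f1": f1,
            "specificity": specificity,
        }
    overall = float(np.trace(cm) / cm.sum()) if cm.sum() else 0.0
    return {"per_class": per_class, "overall_accuracy": overall}


def evaluate(model: RandomForestClassifier, test: pd.DataFrame,
             features=FEATURE_COLUMNS) -> EvaluationReport:
    """Confusion-matrix metrics plus ROC/AUC on a held-out table.

    ROC scores are the fraction of trees voting for the positive
    (Alzheimer) class; AUC by the trapezoidal rule. A one-class test set
    still yields threshold metrics but no ROC.
    """
    _check_table(test, features)
    if len(test) == 0:
        raise ValueError("test table is empty")
    X, y = _xy(test, features)
    pred = model.predict(X)
    cm = confusion_matrix(y, pred, labels=list(LABELS))
    m = metrics_from_confusion(cm)
    roc = auc_val = None
    if len(np.unique(y)) == 2:
        pos_idx = list(model.classes_).index(POSITIVE_LABEL)
        scores = model.predict_proba(X)[:, pos_idx]
        fpr, tpr, thr = roc_curve(y, scores, pos_label=POSITIVE_LABEL)
        roc = (fpr, tpr, thr)
        auc_val = float(_trapezoid_auc(fpr, tpr))
    return EvaluationReport(
        confusion=cm,
        per_class=m["per_class"],
        overall_accuracy=m["overall_accuracy"],
        roc=roc,
        auc=auc_val,
    )


def run_protocol(features_by_group: dict, config: RFConfig = RFConfig(),
                 seed: int = 42, test_fraction: float = 0.20, k: int = 5,
                 mode: str = "paper",
                 features=FEATURE_COLUMNS) -> EvaluationReport:
    """Holdout -> CV on train -> final fit -> test evaluation.

    ``features_by_group`` maps a class label to its per-frame feature
    table (rows flagged invalid are dropped). ``mode="paper"`` splits at
    the frame level (pseudo-replication; a warning is logged);
    ``mode="grouped"`` keeps all frames of one ``source_id`` on one side
    of the holdout split.
    """
    tables = []
    for label, tbl in features_by_group.items():
        tbl = tbl.copy()
        tbl["group_label"] = label
        if "valid" in tbl.columns:
            tbl = tbl[tbl["valid"].astype(bool)]
        tables.append(tbl)
    if len(tables) != 2:
        raise ValueError("run_protocol needs exactly two labeled groups")
    table = pd.concat(tables, ignore_index=True)

    if mode == "paper":
        logger.warning(
            "frame-level splitting: frames from one recording appear on "
            "both sides of the split (pseudo-replication); metrics may be "
            "optimistic for subject-level generalization")
        train, test = holdout_split(table, test_fraction, True, seed)
    elif mode == "grouped":
        gss = GroupShuffleSplit(n_splits=1, test_size=test_fraction,
                                random_state=seed)
        tr_idx, te_idx = next(gss.split(table, groups=table["source_id"]))
        train, test = table.iloc[tr_idx], table.iloc[te_idx]
    else:
        raise ValueError(f"unknown split mode {mode!r}")

    cv = crossval(train, k=k, config=config, seed=seed, features=features)
    model = train_rf(train, config, features)
    report = evaluate(model, test, features)
    report.cv_mean = cv["mean"]
    report.cv_sd = cv["sd"]
    report.cv_ci95_normal = cv["ci95_normal"]
    report.cv_ci95_sd = cv["ci95_sd"]
    return report
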