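"""Nested stratified cross-validated SVM-RBF evaluation with per-fold
wrapper feature selection.

The outer loop is a stratified 10-fold split. Inside each outer training
fold the features are standardized, the selector (PSO, SA, or none) picks a
mask using inner-CV fitness, and an RBF-kernel SVM is trained on the selected
features; the held-out fold is predicted once. Accuracy, sensitivity and
specificity follow the usual confusion-matrix definitions with the
progressive-like group ("B") as the positive class, so sensitivity is the
progressive-detection rate. Headline numbers come from the pooled confusion
counts; fold-averaged metrics are reported alongside. The ROC curve is swept
over the pooled decision values.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as skmetrics
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .selection import (PSOConfig, SAConfig, make_fitness, pso_select,
                        sa_select)

__all__ = [
    "SVMConfig",
    "CVReport",
    "confusion_metrics",
    "roc_curve",
    "nested_cv",
    "report_tables",
]

POSITIVE_CLASS = "B"  # progressive-like group


@dataclasses.dataclass
class SVMConfig:
    cost: float = 1.0
    gamma: str | float = "scale"  # 1/(n_features * feature_variance) rule
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cost <= 0:
            raise ValueError("cost must be > 0")
        if isinstance(self.gamma, (int, float)) and self.gamma <= 0:
            raise ValueError("explicit gamma must be > 0")

    def build(self) -> SVC:
        return SVC(kernel="rbf", C=self.cost, gamma=self.gamma)


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    """Accuracy (TP+TN)/total, sensitivity TP/(TP+FN), specificity TN/(TN+FP);
    a zero denominator flags that rate NaN."""
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("empty confusion matrix")
    return {
        "acc": (tp + tn) / total,
        "sen": tp / (tp + fn) if (tp + fn) > 0 else np.nan,
        "spec": tn / (tn + fp) if (tn + fp) > 0 else np.nan,
    }


def roc_curve(decision_values: np.ndarray, labels: np.ndarray,
              positive: str = POSITIVE_CLASS) -> tuple[np.ndarray, float]:
    """Threshold sweep over the decision values: (FPR, TPR) points and the
    trapezoidal AUC. Ties in the scores step both rates simultaneously."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("ROC needs both classes")
    y = (labels == positive).astype(int)
    fpr, tpr, _ = skmetrics.roc_curve(y, decision_values, drop_intermediate=False)
    points = np.column_stack([fpr, tpr])
    return points, float(skmetrics.auc(fpr, tpr))


@dataclasses.dataclass
class CVReport:
    folds: list[dict]
    pooled: dict[str, float]
    fold_mean: dict[str, float]
    confusion: dict[str, int]
    roc_points: np.ndarray
    auc: float
    selector: str
    seed: int

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        payload["roc_points"] = np.asarray(self.roc_points).tolist()
        return json.dumps(payload, indent=2, default=float)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def _select_mask(x_train, y_train, selector, selector_config, inner_folds, seed,
                 feature_names):
    n = x_train.shape[1]
    if selector == "none":
        return np.ones(n, dtype=bool), None
    fn = make_fitness(x_train, y_train, inner_folds=inner_folds, seed=seed)
    if selector == "pso":
        cfg = selector_config or PSOConfig()
        cfg = dataclasses.replace(cfg, seed=seed)
        result = pso_select(x_train, y_train, config=cfg, fitness_fn=fn)
    elif selector == "sa":
        cfg = selector_config or SAConfig()
        cfg = dataclasses.replace(cfg, seed=seed)
        result = sa_select(x_train, y_train, config=cfg, fitness_fn=fn)
    else:
        raise ValueError(f"unknown selector {selector!r}")
    return result.mask, result


def nested_cv(features: np.ndarray | pd.DataFrame, labels: Sequence[str],
              selector: str = "none",
              selector_config: PSOConfig | SAConfig | None = None,
              svm_config: SVMConfig | None = None,
              outer_folds: int = 10, inner_folds: int = 5,
              seed: int = 0,
              feature_names: Sequence[str] | None = None) -> CVReport:
    """Nested stratified CV with selection confined to the training folds.

    Standardization statistics, the selection mask, and the SVM are all fit
    on the outer-training data only; the held-out fold is touched exactly
    once, for prediction.
    """
    if isinstance(features, pd.DataFrame):
        feature_names = feature_names or list(features.columns)
        features = features.to_numpy(dtype=float)
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    names = np.asarray(feature_names if feature_names is not None
                       else [f"f{i}" for i in range(features.shape[1])])
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size != 2:
        raise ValueError("nested_cv expects exactly two classes")
    if counts.min() < outer_folds:
        raise ValueError("need at least outer_folds subjects per class")

    svm_config = svm_config or SVMConfig(seed=seed)
    cv = StratifiedKFold(n_splits=outer_folds, shuffle=True, random_state=seed)

    folds = []
    pooled_scores = np.empty(labels.size)
    totals = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
    for fold_idx, (train, test) in enumerate(cv.split(features, labels)):
        scaler = StandardScaler().fit(features[train])
        x_train = scaler.transform(features[train])
        x_test = scaler.transform(features[test])
        y_train, y_test = labels[train], labels[test]
        if np.unique(y_test).size < 2:
            raise ValueError(f"outer fold {fold_idx} lost a class")

        mask, _ = _select_mask(x_train, y_train, selector, selector_config,
                               inner_folds, seed + fold_idx, names)
        model = svm_config.build()
        model.fit(x_train[:, mask], y_train)
        pred = model.predict(x_test[:, mask])
        # orient decision scores toward the positive class
        score = model.decision_function(x_test[:, mask])
        if model.classes_[-1] != POSITIVE_CLASS:
            score = -score
        pooled_scores[test] = score

        tp = int(np.sum((pred == POSITIVE_CLASS) & (y_test == POSITIVE_CLASS)))
        fp = int(np.sum((pred == POSITIVE_CLASS) & (y_test != POSITIVE_CLASS)))
        tn = int(np.sum((pred != POSITIVE_CLASS) & (y_test != POSITIVE_CLASS)))
        fn = int(np.sum((pred != POSITIVE_CLASS) & (y_test == POSITIVE_CLASS)))
        for key, val in zip(("tp", "fp", "tn", "fn"), (tp, fp, tn, fn)):
            totals[key] += val
        folds.append({
            "fold": fold_idx, "tp": tp, "fp": fp, "tn": tn, "fn": fn,
            **confusion_metrics(tp, fp, tn, fn),
            "selected_features": list(names[mask]),
            "n_selected": int(mask.sum()),
        })

    pooled = confusion_metrics(**totals)
    fold_mean = {k: float(np.nanmean([f[k] for f in folds]))
                 for k in ("acc", "sen", "spec")}
    points, auc = roc_curve(pooled_scores, labels)
    return CVReport(folds=folds, pooled=pooled, fold_mean=fold_mean,
                    confusion=totals, roc_points=points, auc=auc,
                    selector=selector, seed=seed)


def report_tables(reports: Sequence[tuple[str, str, int, CVReport]]) -> pd.DataFrame:
    """Summary table over tagged runs.

    ``reports`` holds (subset tag, selector, n features extracted, report)
    tuples — the two grouping approaches are: feature families pooled across
    bands (all = 100, graph = 36, MST = 28, triads+TMH+links = 36) and single
    bands across families (25 each).
    """
    seen = set()
    rows = []
    for tag, selector, n_extracted, rep in reports:
        key = (tag, selector)
        if key in seen:
            raise ValueError(f"duplicate report tag {key}")
        seen.add(key)
        n_selected = float(np.mean([f["n_selected"] for f in rep.folds]))
        selected = sorted({name for f in rep.folds for name in f["selected_features"]})
        rows.append({
            "subset": tag,
            "selector": selector,
            "acc": round(rep.pooled["acc"], 4),
            "sen": round(rep.pooled["sen"], 4),
            "spec": round(rep.pooled["spec"], 4),
            "n_extracted": n_extracted,
            "mean_n_selected": n_selected,
            "selected_features": ";".join(selected),
        })
    return pd.DataFrame(rows)


def format_report_text(table: pd.DataFrame) -> str:
    """Aligned fixed-width rendering of a report table."""
    display = table.drop(columns=["selected_features"])
    return display.to_string(index=False)
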