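"""Model diagnostics: confusion-matrix metrics, ROC/AUROC, the
standardisation-rule applicability domain for linear models, and
condition-wise prediction reports.

The +1 class is treated as positive throughout. Percentages are rounded to
two decimals and MCC/AUROC to three in written reports; full precision is
kept internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.metrics import auc, roc_curve

__all__ = [
    "ConfusionMatrix",
    "ClassificationReport",
    "ADReport",
    "classification_metrics",
    "roc_auroc",
    "ad_standardization",
    "condition_wise",
    "evaluate_sets",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")
        if self.total < 1:
            raise ValueError("confusion matrix must count at least one row")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_labels(cls, y_true, y_pred, positive=1) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        if y_true.shape != y_pred.shape:
            raise ValueError("label vectors differ in length")
        pos, neg = y_true == positive, y_true != positive
        ppred = y_pred == positive
        return cls(tp=int((pos & ppred).sum()), tn=int((neg & ~ppred).sum()),
                   fp=int((neg & ppred).sum()), fn=int((pos & ~ppred).sum()))


def classification_metrics(cm: ConfusionMatrix) -> dict:
    """Sensitivity/specificity/accuracy/F1 (all %) and MCC.

    A zero denominator yields ``None`` (undefined), never 0.
    """
    tp, tn, fp, fn = cm.tp, cm.tn, cm.fp, cm.fn

    def pct(num, den):
        return 100.0 * num / den if den else None

    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return {
        "sensitivity_pct": pct(tp, tp + fn),
        "specificity_pct": pct(tn, tn + fp),
        "accuracy_pct": pct(tp + tn, cm.total),
        "f1_pct": pct(2 * tp, 2 * tp + fp + fn),
        "mcc": (tp * tn - fp * fn) / mcc_den if mcc_den else None,
    }


def roc_auroc(scores, labels, positive=1):
    """ROC points by threshold sweep over distinct scores and the trapezoidal
    AUROC. Tied scores share a threshold."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present for a ROC curve")
    fpr, tpr, thresholds = roc_curve(labels, scores, pos_label=positive)
    points = pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})
    return points, float(auc(fpr, tpr))


@dataclass
class ClassificationReport:
    """Per-set confusion matrix + metric block + ROC."""

    sets: dict = field(default_factory=dict)   # set name -> dict of values

    def add_set(self, name: str, y_true, y_pred, scores=None) -> None:
        cm = ConfusionMatrix.from_labels(y_true, y_pred)
        entry = {"cm": cm, **classification_metrics(cm)}
        if scores is not None and len(np.unique(np.asarray(y_true))) == 2:
            points, auroc = roc_auroc(scores, y_true)
            entry["auroc"] = auroc
            entry["roc_points"] = points
        self.sets[name] = entry

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, e in self.sets.items():
            cm = e["cm"]
            row = {"set": name, "TP": cm.tp, "TN": cm.tn, "FP": cm.fp, "FN": cm.fn}
            for key in ("sensitivity_pct", "specificity_pct", "accuracy_pct", "f1_pct"):
                row[key] = None if e[key] is None else round(e[key], 2)
            row["mcc"] = None if e["mcc"] is None else round(e["mcc"], 3)
            if "auroc" in e:
                row["auroc"] = round(e["auroc"], 3)
            rows.append(row)
        return pd.DataFrame(rows)


def evaluate_sets(y_by_set: dict, pred_by_set: dict,
                  scores_by_set: dict | None = None) -> ClassificationReport:
    """Build a report over named sets (sub-training/test/validation)."""
    report = ClassificationReport()
    for name, y in y_by_set.items():
        scores = None if scores_by_set is None else scores_by_set.get(name)
        report.add_set(name, y, pred_by_set[name], scores)
    return report


@dataclass
class ADReport:
    table: pd.DataFrame           # per query row: max_s, mean_s, s_new, in_ad
    n_outliers: int
    skipped_features: list


def ad_standardization(subtrain: pd.DataFrame, query: pd.DataFrame) -> ADReport:
    """Applicability domain by the standardisation rule.

    Each query feature is standardised by sub-training mean/SD to
    S_ik = |x_ik - mu_k| / sd_k. A row is inside the domain if its maximum
    S is <= 3; an outlier if its minimum S exceeds 3; otherwise it is an
    outlier iff mean(S) + 1.28 * SD(S) > 3.
    """
    missing = [c for c in subtrain.columns if c not in query.columns]
    if missing:
        raise ValueError(f"query rows lack features {missing}")
    query = query[list(subtrain.columns)]
    mu = subtrain.mean(axis=0)
    sd = subtrain.std(axis=0, ddof=1)
    skipped = [c for c in subtrain.columns if sd[c] == 0 or np.isnan(sd[c])]
    cols = [c for c in subtrain.columns if c not in set(skipped)]
    if not cols:
        raise ValueError("no feature has positive sub-training variance")
    S = (query[cols] - mu[cols]).abs() / sd[cols]
    s = S.to_numpy(dtype=float)
    max_s = s.max(axis=1)
    min_s = s.min(axis=1)
    mean_s = s.mean(axis=1)
    sd_s = s.std(axis=1, ddof=1) if s.shape[1] > 1 else np.zeros(len(s))
    s_new = mean_s + 1.28 * sd_s

    outlier = np.where(max_s <= 3.0, False,
                       np.where(min_s > 3.0, True, s_new > 3.0))
    table = pd.DataFrame({
        "max_s": max_s, "min_s": min_s, "mean_s": mean_s, "s_new": s_new,
        "in_ad": ~outlier,
    }, index=query.index)
    return ADReport(table=table, n_outliers=int(outlier.sum()),
                    skipped_features=skipped)


def condition_wise(y_pred, y_true, conditions: pd.DataFrame, set_labels,
                   sets=("test", "validation"), min_count: int = 1) -> pd.DataFrame:
    """Per-condition-tuple instance counts and % accuracy per set.

    Cells for a tuple absent from a set read "na". Tuples whose accuracy is
    0 in some set, or whose instance count is <= ``min_count`` everywhere it
    appears, are flagged for review.
    """
    y_pred = np.asarray(y_pred)
    y_true = np.asarray(y_true)
    set_labels = np.asarray(set_labels)
    if not (len(y_pred) == len(y_true) == len(conditions) == len(set_labels)):
        raise ValueError("input vectors differ in length")

    tuples = list(map(tuple, conditions.to_numpy()))
    uniq = sorted({t for t, s in zip(tuples, set_labels) if s in sets})
    rows = []
    for t in uniq:
        row = {col: val for col, val in zip(conditions.columns, t)}
        flag = False
        low_count = True
        for s in sets:
            sel = np.array([tt == t and sl == s
                            for tt, sl in zip(tuples, set_labels)])
            n = int(sel.sum())
            if n == 0:
                row[f"{s}_n"] = "na"
                row[f"{s}_accuracy_pct"] = "na"
                continue
            acc = 100.0 * float((y_pred[sel] == y_true[sel]).mean())
            row[f"{s}_n"] = n
            row[f"{s}_accuracy_pct"] = round(acc, 2)
            if acc == 0.0:
                flag = True
            if n > min_count:
                low_count = False
        row["flagged"] = bool(flag or low_count)
        rows.append(row)
    return pd.DataFrame(rows)
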