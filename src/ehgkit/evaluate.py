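"""Classifier performance metrics and across-partition aggregation.

All metrics are expressed in percent. Confusion-based metrics use a
fixed score threshold (0.5 by default); ROC/AUC are threshold-free, with
the AUC equal to the Mann-Whitney probability that a random positive
outscores a random negative (ties counted half).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

METRIC_NAMES = ("accuracy", "auc", "f1", "sensitivity", "specificity", "ppv", "npv")
SPLIT_NAMES = ("train", "validation", "test")
FPR_GRID = np.linspace(0.0, 1.0, 101)


def confusion(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> tuple[int, int, int, int]:
    """(TP, TN, FP, FN) at the given score threshold.

    A positive call is score >= threshold; a true positive is an
    imminent-labor recording called positive.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must align")
    pred = (s >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    return tp, tn, fp, fn


def metrics_from_confusion(tp: int, tn: int, fp: int, fn: int) -> dict[str, float]:
    """The six confusion-count metrics, in percent.

    accuracy    = (TP+TN) / (TP+TN+FP+FN)
    sensitivity = TP / (TP+FN)          specificity = TN / (TN+FP)
    PPV         = TP / (TP+FP)          NPV         = TN / (TN+FN)
    F1          = 2 TP / (2 TP + FP + FN)

    A metric whose denominator is zero comes back NaN (undefined); the
    others are still returned.
    """
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("empty confusion matrix")

    def ratio(num: float, den: float) -> float:
        return 100.0 * num / den if den > 0 else float("nan")

    return {
        "accuracy": ratio(tp + tn, total),
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
        "f1": ratio(2 * tp, 2 * tp + fp + fn),
    }


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """(fpr, tpr, AUC%) of the score; AUC by trapezoid over the ROC.

    Equals the pairwise Mann-Whitney estimate with ties counted half.
    Raises on single-class input, where the ROC is undefined.
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC undefined: only one class present")
    fpr, tpr, _ = roc_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, 100.0 * auc


def metric_set(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> dict[str, float]:
    """All seven metrics (percent) for one scored dataset."""
    tp, tn, fp, fn = confusion(scores, labels, threshold)
    out = metrics_from_confusion(tp, tn, fp, fn)
    try:
        _, _, out["auc"] = roc_auc(scores, labels)
    except ValueError:
        out["auc"] = float("nan")
    return out


@dataclass
class PartitionResult:
    """Everything recorded for one holdout partition."""

    partition_id: int
    hidden_n: int
    n_components: int
    metrics: dict[str, dict[str, float]]  # split -> metric -> percent
    test_scores: np.ndarray
    test_labels: np.ndarray
    test_confusion: tuple[int, int, int, int]
    valid: bool = True
    failure: str = ""


@dataclass
class StudyReport:
    """Across-partition summary for one (input set, horizon) model."""

    table: pd.DataFrame  # index metric, columns (split, mean|sd)
    mean_roc: pd.DataFrame  # columns fpr, tpr_mean, tpr_sd
    mean_confusion: pd.DataFrame  # 2x2 mean counts
    n_partitions: int
    hidden_counts: dict[int, int] = field(default_factory=dict)


def aggregate_report(results: list[PartitionResult]) -> StudyReport:
    """Mean +/- SD of every metric over valid partitions, the vertically
    averaged test ROC (mean TPR on a fixed 101-point FPR grid) and the
    arithmetic mean test confusion matrix.

    SD is the sample (n-1) standard deviation; with one partition it is
    reported as 0. Aggregation ignores partitions flagged invalid.
    """
    valid = [r for r in results if r.valid]
    if not valid:
        raise ValueError("no valid partitions to aggregate")

    cells: dict[tuple[str, str], tuple[float, float]] = {}
    for split in SPLIT_NAMES:
        for metric in METRIC_NAMES:
            vals = np.array([r.metrics[split][metric] for r in valid], dtype=float)
            vals = vals[~np.isnan(vals)]
            if vals.size == 0:
                cells[(split, metric)] = (float("nan"), float("nan"))
            else:
                sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
                cells[(split, metric)] = (float(vals.mean()), sd)
    table = pd.DataFrame(
        {
            (split, stat): [
                cells[(split, metric)][0 if stat == "mean" else 1]
                for metric in METRIC_NAMES
            ]
            for split in SPLIT_NAMES
            for stat in ("mean", "sd")
        },
        index=list(METRIC_NAMES),
    )
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["split", "stat"])

    tprs = []
    for r in valid:
        fpr, tpr, _ = roc_auc(r.test_scores, r.test_labels)
        tprs.append(np.interp(FPR_GRID, fpr, tpr))
    tpr_arr = np.vstack(tprs)
    mean_roc = pd.DataFrame(
        {
            "fpr": FPR_GRID,
            "tpr_mean": tpr_arr.mean(axis=0),
            "tpr_sd": tpr_arr.std(axis=0, ddof=1) if len(valid) > 1 else np.zeros_like(FPR_GRID),
        }
    )

    conf = np.array([r.test_confusion for r in valid], dtype=float).mean(axis=0)
    tp, tn, fp, fn = conf
    mean_confusion = pd.DataFrame(
        [[tp, fn], [fp, tn]],
        index=pd.Index(["actual_pos", "actual_neg"]),
        columns=pd.Index(["pred_pos", "pred_neg"]),
    )

    hidden_counts: dict[int, int] = {}
    for r in valid:
        hidden_counts[r.hidden_n] = hidden_counts.get(r.hidden_n, 0) + 1

    return StudyReport(
        table=table,
        mean_roc=mean_roc,
        mean_confusion=mean_confusion,
        n_partitions=len(valid),
        hidden_counts=hidden_counts,
    )


def report_to_frame(report: StudyReport) -> pd.DataFrame:
    """Flat tidy view of the report table (metric, split, mean, sd)."""
    rows = []
    for metric in METRIC_NAMES:
        for split in SPLIT_NAMES:
            rows.append(
                {
                    "metric": metric,
                    "split": split,
                    "mean": report.table.loc[metric, (split, "mean")],
                    "sd": report.table.loc[metric, (split, "sd")],
                }
            )
    return pd.DataFrame(rows)
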