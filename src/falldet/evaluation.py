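"""Per-event evaluation: one-vs-rest confusion counts, accuracy /
sensitivity / specificity, ROC sweeps, and the replicate report.

Because the block population is heavily imbalanced (daily-living activity
dominates), pooled accuracy is uninformative and is never reported; every
metric is computed per event class from one-vs-rest counts:

    accuracy_c    = (TP_c + TN_c) / (TP_c + TN_c + FP_c + FN_c)
    sensitivity_c =  TP_c / (TP_c + FN_c)        (true-positive rate)
    specificity_c =  TN_c / (TN_c + FP_c)        (true-negative rate)

A 0/0 cell is reported as missing (NaN), never silently as 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc

from .architecture import fuse_batch
from .io_formats import BlockDataset
from .labels import ClassLabel, N_CLASSES


@dataclass
class ConfusionCounts:
    """One-vs-rest counts per class, derived from the full confusion matrix."""

    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray
    matrix: np.ndarray          # (C, C), rows = truth, cols = prediction

    @property
    def total(self) -> int:
        return int(self.matrix.sum())


def confusion_counts(pred, truth, n_classes: int = N_CLASSES) -> ConfusionCounts:
    pred = np.asarray(pred, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if pred.shape != truth.shape:
        raise ValueError(f"pred shape {pred.shape} != truth shape {truth.shape}")
    if pred.size == 0:
        raise ValueError("cannot compute confusion counts on empty inputs")
    m = _sk_confusion(truth, pred, labels=np.arange(n_classes))
    tp = np.diag(m).astype(np.int64)
    fn = m.sum(axis=1) - tp
    fp = m.sum(axis=0) - tp
    tn = m.sum() - tp - fn - fp
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn, matrix=m)


@dataclass
class ClassMetrics:
    accuracy: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        idx = [ClassLabel(c).name for c in range(len(self.accuracy))]
        return pd.DataFrame(
            {
                "accuracy": self.accuracy,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            },
            index=pd.Index(idx, name="event"),
        )


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.full(num.shape, np.nan, dtype=float)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def class_metrics(counts: ConfusionCounts) -> ClassMetrics:
    """Exact per-event accuracy/sensitivity/specificity; 0/0 -> NaN."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    return ClassMetrics(
        accuracy=_safe_ratio(tp + tn, tp + tn + fp + fn),
        sensitivity=_safe_ratio(tp, tp + fn),
        specificity=_safe_ratio(tn, tn + fp),
    )


# --------------------------------------------------------------------------
# ROC
# --------------------------------------------------------------------------

def roc_points(
    scores: np.ndarray,
    truth,
    cls: ClassLabel | int,
) -> np.ndarray:
    """One-vs-rest ROC points for one class, sweeping its score column.

    Returns an (m, 2) array of (FPR, TPR) sorted by FPR, including the
    (0, 0) and (1, 1) endpoints.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    positive = (truth == int(cls)).astype(int)
    if positive.all() or not positive.any():
        raise ValueError(
            f"degenerate ROC: test truth contains a single class for {cls!r}"
        )
    col = scores[:, int(cls)]
    fpr, tpr, _ = _sk_roc(positive, col, drop_intermediate=False)
    pts = np.column_stack([fpr, tpr])
    for endpoint in ((0.0, 0.0), (1.0, 1.0)):
        if not np.any((pts == endpoint).all(axis=1)):
            pts = np.vstack([pts, endpoint])
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    return pts[order]


def roc_auc(points: np.ndarray) -> float:
    """Trapezoidal area under an (FPR, TPR) point list."""
    return float(np.trapezoid(points[:, 1], points[:, 0]))


# --------------------------------------------------------------------------
# Report
# --------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Per-event metric table (mean +- sd over replicates), confusion
    matrix, and per-class ROC points."""

    metrics: pd.DataFrame       # rows = events; mean columns, sd when >1 run
    confusion: pd.DataFrame     # 3x3, first run (rows truth, cols pred)
    roc: dict[str, np.ndarray]  # class name -> (m, 2) points
    n_runs: int

    def write(self, outdir: Path | str) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.metrics.to_csv(outdir / "metrics.csv")
        self.confusion.to_csv(outdir / "confusion_matrix.csv")
        for name, pts in self.roc.items():
            pd.DataFrame(pts, columns=["fpr", "tpr"]).to_csv(
                outdir / f"roc_{name.lower()}.csv", index=False
            )


def _predictions(model, test: BlockDataset) -> tuple[np.ndarray, np.ndarray]:
    scores = np.concatenate([
        model.scores(test.X[i:i + 512]) for i in range(0, len(test), 512)
    ])
    return scores, fuse_batch(scores)


def evaluation_report(
    model_or_models,
    test: BlockDataset,
) -> EvaluationReport:
    """Evaluate one trained model (or a replicate list) on the test split.

    With several models the metric table carries mean and sd columns; the
    confusion matrix and ROC points are those of the first run.
    """
    if len(test) == 0:
        raise ValueError("test set is empty")
    models = (model_or_models if isinstance(model_or_models, (list, tuple))
              else [model_or_models])
    per_run: list[pd.DataFrame] = []
    first_counts = None
    first_scores = None
    for model in models:
        scores, pred = _predictions(model, test)
        counts = confusion_counts(pred, test.y)
        per_run.append(class_metrics(counts).as_frame())
        if first_counts is None:
            first_counts, first_scores = counts, scores

    stacked = pd.concat(per_run, keys=range(len(per_run)))
    mean = stacked.groupby(level=1, sort=False).mean()
    if len(per_run) > 1:
        sd = stacked.groupby(level=1, sort=False).std(ddof=1)
        metrics = mean.join(sd, lsuffix="_mean", rsuffix="_sd")
    else:
        metrics = mean

    names = [ClassLabel(c).name for c in range(first_counts.matrix.shape[0])]
    confusion = pd.DataFrame(first_counts.matrix, index=pd.Index(names, name="truth"),
                             columns=pd.Index(names, name="predicted"))
    roc = {}
    for c in range(len(names)):
        try:
            roc[names[c]] = roc_points(first_scores, test.y, c)
        except ValueError:
            continue  # class absent from (or filling) the test labels
    return EvaluationReport(
        metrics=metrics, confusion=confusion, roc=roc, n_runs=len(models)
    )
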