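"""Classification/regression metrics and the cross-validation harness.

ACC, MCC, BCE, AUC, PR-AUC and R-squared are implemented directly from their
defining formulas (AUC via the tie-corrected Mann-Whitney statistic, PR-AUC by
step integration of precision over recall) so they can be cross-checked
against independent library implementations in tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_metrics",
    "confusion_from_predictions",
    "bce_loss",
    "ranking_metrics",
    "r_squared",
    "cross_validate",
]

EPS = 1e-7


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_from_predictions(
    labels: Sequence[int], probs: Sequence[float], threshold: float = 0.5
) -> ConfusionCounts:
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probs, dtype=float)
    pred = (p >= threshold).astype(int)
    return ConfusionCounts(
        tp=int(((pred == 1) & (y == 1)).sum()),
        tn=int(((pred == 0) & (y == 0)).sum()),
        fp=int(((pred == 1) & (y == 0)).sum()),
        fn=int(((pred == 0) & (y == 1)).sum()),
    )


def confusion_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Accuracy and Matthews correlation from confusion counts.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); a zero
    denominator yields MCC = 0 by convention.
    """
    if counts.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    tp, tn, fp, fn = (float(v) for v in (counts.tp, counts.tn, counts.fp, counts.fn))
    acc = (tp + tn) / (tp + tn + fp + fn)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / np.sqrt(denom)
    return {"acc": acc, "mcc": mcc}


def bce_loss(labels: Sequence[int], probs: Sequence[float]) -> float:
    """Mean binary cross-entropy; probabilities clamped into (eps, 1-eps)."""
    y = np.asarray(labels, dtype=float)
    p = np.clip(np.asarray(probs, dtype=float), EPS, 1.0 - EPS)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} labels vs {p.shape} probabilities")
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def ranking_metrics(labels: Sequence[int], scores: Sequence[float]) -> dict[str, float]:
    """AUC (tie-corrected Mann-Whitney) and PR-AUC (step integration)."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for ranking metrics")

    # AUC: mean rank of positives, ties get average rank
    order = np.argsort(s, kind="mergesort")
    ranks = np.empty(len(s), dtype=float)
    ranks[order] = np.arange(1, len(s) + 1)
    for val in np.unique(s):
        mask = s == val
        if mask.sum() > 1:
            ranks[mask] = ranks[mask].mean()
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    # PR-AUC: walk thresholds from high to low score, conservative steps
    desc = np.argsort(-s, kind="mergesort")
    y_desc = y[desc]
    s_desc = s[desc]
    tp = np.cumsum(y_desc)
    fp = np.cumsum(1 - y_desc)
    # only evaluate at the last index of each distinct score (threshold points)
    distinct = np.flatnonzero(np.r_[s_desc[1:] != s_desc[:-1], True])
    precision = tp[distinct] / (tp[distinct] + fp[distinct])
    recall = tp[distinct] / n_pos
    pr_auc = 0.0
    prev_recall = 0.0
    for prec, rec in zip(precision, recall):
        pr_auc += prec * (rec - prev_recall)
        prev_recall = rec
    return {"auc": float(auc), "pr_auc": float(pr_auc)}


def r_squared(targets: Sequence[float], predictions: Sequence[float]) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot."""
    t = np.asarray(targets, dtype=float)
    p = np.asarray(predictions, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 targets")
    ss_tot = float(((t - t.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise ValueError("target variance is zero; R^2 undefined")
    ss_res = float(((t - p) ** 2).sum())
    return 1.0 - ss_res / ss_tot


@dataclass
class MetricReport:
    """Per-fold metric values with mean +/- sd summaries."""

    per_fold: dict[str, list[float]] = field(default_factory=dict)
    predictions: list[dict] = field(default_factory=list)  # inchikey, fold, y, p
    skipped_folds: list[int] = field(default_factory=list)

    def add_fold(self, metrics: dict[str, float]) -> None:
        for k, v in metrics.items():
            self.per_fold.setdefault(k, []).append(float(v))

    def summary(self) -> dict[str, dict[str, float]]:
        out = {}
        for k, vals in self.per_fold.items():
            arr = np.asarray(vals)
            out[k] = {"mean": float(arr.mean()), "sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0}
        return out

    def to_dict(self) -> dict:
        return {"per_fold": self.per_fold, "summary": self.summary(), "skipped_folds": self.skipped_folds}


def cross_validate(
    model_builder: Callable,
    records: Sequence,
    folds: Sequence[int],
    metric_names: Sequence[str] = ("acc", "mcc", "auc", "bce"),
    seed: int = 0,
) -> MetricReport:
    """k-fold cross-validation over pre-assigned folds.

    ``model_builder(train_records, seed)`` must return an object with a
    ``predict_proba(records) -> array`` method.  Folds whose training split
    contains a single class are skipped with a warning and reported.
    """
    records = list(records)
    folds = np.asarray(folds, dtype=int)
    if len(folds) != len(records):
        raise ValueError("folds must cover records")
    report = MetricReport()
    for fold in sorted(set(folds.tolist())):
        test_idx = np.flatnonzero(folds == fold)
        train_idx = np.flatnonzero(folds != fold)
        train = [records[i] for i in train_idx]
        test = [records[i] for i in test_idx]
        y_train = {getattr(r, "label", None) for r in train}
        y_train.discard(None)
        if len({int(v) for v in y_train}) < 2:
            warnings.warn(f"fold {fold}: single-class training split; skipped")
            report.skipped_folds.append(int(fold))
            continue
        model = model_builder(train, seed + fold)
        probs = np.asarray(model.predict_proba(test), dtype=float)
        y_test = np.asarray([int(r.label) for r in test])
        fold_metrics: dict[str, float] = {}
        counts = confusion_from_predictions(y_test, probs)
        cm = confusion_metrics(counts)
        if "acc" in metric_names:
            fold_metrics["acc"] = cm["acc"]
        if "mcc" in metric_names:
            fold_metrics["mcc"] = cm["mcc"]
        if "bce" in metric_names:
            fold_metrics["bce"] = bce_loss(y_test, probs)
        if ("auc" in metric_names or "pr_auc" in metric_names) and len(set(y_test.tolist())) == 2:
            rm = ranking_metrics(y_test, probs)
            if "auc" in metric_names:
                fold_metrics["auc"] = rm["auc"]
            if "pr_auc" in metric_names:
                fold_metrics["pr_auc"] = rm["pr_auc"]
        report.add_fold(fold_metrics)
        for j, (i, rec) in enumerate(zip(test_idx, test)):
            report.predictions.append(
                {
                    "inchikey": getattr(getattr(rec, "record", rec), "inchikey", str(i)),
                    "fold": int(fold),
                    "y": int(rec.label),
                    "p": float(probs[j]),
                }
            )
    return report
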