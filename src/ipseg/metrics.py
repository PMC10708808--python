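"""Binary segmentation evaluation: Dice, Jaccard, Precision, Recall, F-Measure.

All five scores are computed from the pixelwise confusion counts between a
predicted mask and a ground-truth mask:

    Dice      = 2|P∩G| / (|P| + |G|)
    Jaccard   = |P∩G| / |P∪G|
    Precision = TP / (TP + FP)
    Recall    = TP / (TP + FN)
    F-Measure = (a²+1)·Precision·Recall / (a²·(Precision + Recall)),  a = 1

At a=1 the F-Measure coincides with Dice for binary masks.

Degenerate masks: when both masks are empty every score is 1 (perfect
agreement on "nothing to segment"); when exactly one is empty the overlap
scores are 0, precision is 1 only if the prediction is empty, and recall is 1
only if the ground truth is empty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BinaryMask",
    "ConfusionCounts",
    "MetricsConfig",
    "MetricsReport",
    "confusion_counts",
    "dice",
    "jaccard",
    "precision",
    "recall",
    "f_measure",
    "evaluate_masks",
    "scores_to_mask",
    "summarize_reports",
]

BinaryMask = np.ndarray  # 2D array with values in {0, 1}


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsConfig:
    """a: F-Measure precision/recall balance; empty_both_value: score when
    both masks are empty."""

    a: float = 1.0
    empty_both_value: float = 1.0


@dataclass(frozen=True)
class MetricsReport:
    dice: float
    jaccard: float
    precision: float
    recall: float
    f_measure: float
    counts: ConfusionCounts

    def as_dict(self) -> dict[str, float]:
        return {"dice": self.dice, "jaccard": self.jaccard,
                "precision": self.precision, "recall": self.recall,
                "f_measure": self.f_measure}


def _validate_pair(pred: BinaryMask, gt: BinaryMask) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {gt.shape}")
    for name, m in (("pred", pred), ("gt", gt)):
        vals = np.unique(m)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"{name} mask is not binary (values {vals[:5]}...)")
    return pred.astype(bool), gt.astype(bool)


def confusion_counts(pred: BinaryMask, gt: BinaryMask) -> ConfusionCounts:
    """Exact pixel tallies of TP/FP/FN/TN between two equal-shape binary masks."""
    p, g = _validate_pair(pred, gt)
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = int(np.count_nonzero(~p & ~g))
    return ConfusionCounts(tp, fp, fn, tn)


def _overlap_score(num: float, den: float, both_empty: bool,
                   cfg: MetricsConfig) -> float:
    if both_empty:
        return cfg.empty_both_value
    return num / den if den > 0 else 0.0


def dice(pred: BinaryMask, gt: BinaryMask,
         cfg: MetricsConfig = MetricsConfig()) -> float:
    c = confusion_counts(pred, gt)
    return _overlap_score(2.0 * c.tp, 2.0 * c.tp + c.fp + c.fn,
                          c.tp + c.fp + c.fn == 0, cfg)


def jaccard(pred: BinaryMask, gt: BinaryMask,
            cfg: MetricsConfig = MetricsConfig()) -> float:
    c = confusion_counts(pred, gt)
    return _overlap_score(float(c.tp), float(c.tp + c.fp + c.fn),
                          c.tp + c.fp + c.fn == 0, cfg)


def precision(pred: BinaryMask, gt: BinaryMask,
              cfg: MetricsConfig = MetricsConfig()) -> float:
    c = confusion_counts(pred, gt)
    if c.tp + c.fp + c.fn == 0:
        return cfg.empty_both_value
    if c.tp + c.fp == 0:  # empty prediction: vacuously precise
        return 1.0
    return c.tp / (c.tp + c.fp)


def recall(pred: BinaryMask, gt: BinaryMask,
           cfg: MetricsConfig = MetricsConfig()) -> float:
    c = confusion_counts(pred, gt)
    if c.tp + c.fp + c.fn == 0:
        return cfg.empty_both_value
    if c.tp + c.fn == 0:  # empty ground truth: nothing to miss
        return 1.0
    return c.tp / (c.tp + c.fn)


def f_measure(pred: BinaryMask, gt: BinaryMask,
              cfg: MetricsConfig = MetricsConfig()) -> float:
    c = confusion_counts(pred, gt)
    if c.tp + c.fp + c.fn == 0:
        return cfg.empty_both_value
    p = precision(pred, gt, cfg)
    r = recall(pred, gt, cfg)
    if p + r == 0 or (c.tp == 0):
        return 0.0
    a2 = cfg.a ** 2
    return (a2 + 1.0) * p * r / (a2 * (p + r))


def evaluate_masks(pred: BinaryMask, gt: BinaryMask,
                   cfg: MetricsConfig = MetricsConfig()) -> MetricsReport:
    """All five scores plus the confusion counts for one mask pair."""
    c = confusion_counts(pred, gt)
    return MetricsReport(
        dice=dice(pred, gt, cfg),
        jaccard=jaccard(pred, gt, cfg),
        precision=precision(pred, gt, cfg),
        recall=recall(pred, gt, cfg),
        f_measure=f_measure(pred, gt, cfg),
        counts=c,
    )


def scores_to_mask(scores: np.ndarray) -> BinaryMask:
    """Argmax over per-class score maps (K,H,W) -> {0,1} mask (class 1 = fg)."""
    scores = np.asarray(scores)
    if scores.ndim != 3 or scores.shape[0] < 2:
        raise ValueError("expected (n_classes>=2, H, W) score maps")
    return (np.argmax(scores, axis=0) == 1).astype(np.uint8)


def summarize_reports(reports: list[MetricsReport]) -> pd.DataFrame:
    """Per-image table of metric columns; dataset scores are column means."""
    rows = []
    for r in reports:
        row = r.as_dict()
        row.update(tp=r.counts.tp, fp=r.counts.fp, fn=r.counts.fn, tn=r.counts.tn)
        rows.append(row)
    return pd.DataFrame(rows)
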