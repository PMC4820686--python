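"""Segmentation evaluation: confusion counts and the derived metrics.

With TP/FP/FN/TN pixel tallies against a manual (ground-truth) mask:

    accuracy    = (TP + TN) / (TP + FP + FN + TN)
    overlap     = TP / (TP + FP + FN)          (Jaccard index)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)

Both per-slice and pooled (counts summed over slices) aggregations are
provided, since averaged and pooled values differ when slice areas vary.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np

from .io import as_binary_mask

__all__ = ["ConfusionCounts", "MetricReport", "confusion", "compute_metrics", "evaluate_stack"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )


@dataclass(frozen=True)
class MetricReport:
    accuracy: float
    overlap: float
    sensitivity: float
    specificity: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixel-wise confusion counts of a predicted vs. a manual mask."""
    p = as_binary_mask(pred)
    t = as_binary_mask(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)),
        tn=int(np.sum(~p & ~t)),
    )


def _ratio(num: int, den: int, empty_value: float = 1.0) -> float:
    return num / den if den > 0 else empty_value


def compute_metrics(c: ConfusionCounts) -> MetricReport:
    """Metrics from confusion counts.

    0/0 conventions: sensitivity is 1 when the truth is empty, specificity
    is 1 when the truth covers everything, overlap is 1 when both masks are
    empty.
    """
    if c.total <= 0:
        raise ValueError("empty confusion table")
    return MetricReport(
        accuracy=(c.tp + c.tn) / c.total,
        overlap=_ratio(c.tp, c.tp + c.fp + c.fn),
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
    )


def evaluate_stack(
    preds: Sequence[np.ndarray], truths: Sequence[np.ndarray]
) -> dict[str, object]:
    """Per-slice and pooled evaluation of a mask stack.

    Pooled metrics sum the confusion counts over slices before dividing;
    per-slice metrics are also averaged with equal slice weight.
    """
    if len(preds) != len(truths):
        raise ValueError("pred and truth stacks differ in length")
    if not preds:
        raise ValueError("empty stacks")
    per_slice = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    for p, t in zip(preds, truths):
        c = confusion(p, t)
        pooled = pooled + c
        per_slice.append({"counts": asdict(c), "metrics": compute_metrics(c).as_dict()})
    mean = {
        k: float(np.mean([s["metrics"][k] for s in per_slice]))
        for k in ("accuracy", "overlap", "sensitivity", "specificity")
    }
    return {
        "per_slice": per_slice,
        "pooled_counts": asdict(pooled),
        "pooled": compute_metrics(pooled).as_dict(),
        "mean_per_slice": mean,
    }
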