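"""Pixel-wise segmentation evaluation metrics.

Six standard measures comparing a segmentation result SR against a
ground-truth mask GT, all derived from the pixel confusion counts:

    accuracy     AC  = (TP + TN) / (TP + TN + FP + FN)
    sensitivity  SE  = TP / (TP + FN)
    specificity  SP  = TN / (TN + FP)
    Dice         DSC = 2|GT & SR| / (|GT| + |SR|)
    Jaccard      JS  = |GT & SR| / |GT | SR|
    MSE              = mean((GT - SR)^2), averaged over images in batch form

Conventions for empty denominators (both masks empty, or a class
absent): similarity measures default to 1 and error measures to 0, so a
perfect trivial agreement scores perfectly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["ConfusionCounts", "MetricReport", "confusion", "evaluate", "evaluate_batch"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricReport:
    dsc: float
    js: float
    accuracy: float
    sensitivity: float
    specificity: float
    mse: float


def _as_binary(mask: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.dtype != bool:
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"{name} is not binary (values {vals[:5]}...)")
        arr = arr.astype(bool)
    return arr


def confusion(gt: np.ndarray, sr: np.ndarray) -> ConfusionCounts:
    gt = _as_binary(gt, "GT")
    sr = _as_binary(sr, "SR")
    if gt.shape != sr.shape:
        raise ValueError(f"shape mismatch: GT {gt.shape} vs SR {sr.shape}")
    tp = int(np.sum(gt & sr))
    tn = int(np.sum(~gt & ~sr))
    fp = int(np.sum(~gt & sr))
    fn = int(np.sum(gt & ~sr))
    return ConfusionCounts(tp, tn, fp, fn)


def _ratio(num: float, den: float, empty: float) -> float:
    return num / den if den > 0 else empty


def evaluate(gt: np.ndarray, sr: np.ndarray) -> MetricReport:
    """All six metrics for one GT/SR mask pair."""
    c = confusion(gt, sr)
    inter = c.tp
    union = c.tp + c.fp + c.fn
    return MetricReport(
        dsc=_ratio(2.0 * inter, 2.0 * c.tp + c.fp + c.fn, 1.0),
        js=_ratio(float(inter), float(union), 1.0),
        accuracy=_ratio(float(c.tp + c.tn), float(c.total), 1.0),
        sensitivity=_ratio(float(c.tp), float(c.tp + c.fn), 1.0),
        specificity=_ratio(float(c.tn), float(c.tn + c.fp), 1.0),
        mse=_ratio(float(c.fp + c.fn), float(c.total), 0.0),
    )


def evaluate_batch(gts: Sequence[np.ndarray], srs: Sequence[np.ndarray]):
    """Per-image reports plus the mean +- sd summary across N images.

    The batch MSE follows the 1/N averaged form: the mean over images of
    each image's mean squared pixel difference.
    """
    if len(gts) != len(srs):
        raise ValueError("GT and SR sequences differ in length")
    reports = [evaluate(g, s) for g, s in zip(gts, srs)]
    fields = ("dsc", "js", "accuracy", "sensitivity", "specificity", "mse")
    summary = {
        f: (float(np.mean([getattr(r, f) for r in reports])),
            float(np.std([getattr(r, f) for r in reports])))
        for f in fields
    }
    return reports, summary
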