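"""Validation metrics at patch level and pixel level.

All metrics derive from one-vs-rest confusion counts:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    error rate  = (FP + FN) / (TP + TN + FP + FN)
    PPV         = TP / (TP + FP)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)

Ratios with a zero denominator are reported as NaN and flagged, never
silently zeroed.  Pixel-level evaluation is restricted to the field of view
when one is present, so the black surround cannot inflate the true-negative
count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .errors import InvalidInputError
from .image import CLASSES, CLASS_INDEX, SIGNS
from .segmentation import SegmentationResult


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest confusion counts for a single positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise InvalidInputError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """The five validation metrics for one class at one evaluation level."""

    accuracy: float
    error_rate: float
    ppv: float
    sensitivity: float
    specificity: float
    level: str = "patch"  # "patch" | "pixel"
    undefined: tuple[str, ...] = field(default=())

    def as_dict(self) -> dict[str, float]:
        return dict(
            accuracy=self.accuracy, error_rate=self.error_rate, ppv=self.ppv,
            sensitivity=self.sensitivity, specificity=self.specificity,
        )


def confusion(predicted, truth, positive_class) -> ConfusionCounts:
    """One-vs-rest counts of ``positive_class`` between two label arrays."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise InvalidInputError("predicted and truth must have equal length")
    p = predicted == positive_class
    t = truth == positive_class
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        tn=int(np.sum(~p & ~t)),
        fn=int(np.sum(~p & t)),
    )


def compute_metrics(counts: ConfusionCounts, level: str = "patch") -> MetricsReport:
    """The five metrics from one count set.

    ``error_rate`` is computed as ``1 - accuracy`` (algebraically identical
    to (FP+FN)/total) so the accuracy + error identity holds exactly in
    floating point.
    """
    if counts.total == 0:
        raise InvalidInputError("cannot compute metrics from zero counts")
    undefined = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    accuracy = (counts.tp + counts.tn) / counts.total
    return MetricsReport(
        accuracy=accuracy,
        error_rate=1.0 - accuracy,
        ppv=ratio(counts.tp, counts.tp + counts.fp, "ppv"),
        sensitivity=ratio(counts.tp, counts.tp + counts.fn, "sensitivity"),
        specificity=ratio(counts.tn, counts.tn + counts.fp, "specificity"),
        level=level,
        undefined=tuple(undefined),
    )


def evaluate_patches(model, test_patches) -> dict[str, dict]:
    """Patch-level evaluation of a trained classifier.

    Each patch is classified by argmax probability.  Returns, per class, the
    one-vs-rest :class:`MetricsReport` plus the score/truth arrays needed
    for ROC plotting.
    """
    from .nn.train import patches_to_arrays

    if not test_patches:
        raise InvalidInputError("empty test set")
    x, y = patches_to_arrays(test_patches)
    probs = model.predict_proba(model.prepare_input(x), prepared=True)
    predicted = probs.argmax(axis=1)
    out: dict[str, dict] = {}
    for cls in CLASSES:
        idx = CLASS_INDEX[cls]
        counts = confusion(predicted, y, idx)
        out[cls] = dict(
            report=compute_metrics(counts, level="patch"),
            counts=counts,
            scores=probs[:, idx],
            truth=(y == idx),
        )
    return out


def roc_points(scores: np.ndarray, truth: np.ndarray) -> pd.DataFrame:
    """ROC coordinates (fpr, tpr, threshold) for one class's scores."""
    fpr, tpr, thr = roc_curve(np.asarray(truth, bool), np.asarray(scores, float))
    return pd.DataFrame(dict(fpr=fpr, tpr=tpr, threshold=thr))


#: Seeds used when averaging patch-level results over repeated runs.
DEFAULT_REPETITION_SEEDS = tuple(range(10))


def mean_over_repetitions(
    run_fn, seeds=DEFAULT_REPETITION_SEEDS
) -> dict[str, MetricsReport]:
    """Mean per-class metrics of repeated train/evaluate runs.

    ``run_fn(seed)`` must return a mapping class -> :class:`MetricsReport`
    (or the dicts produced by :func:`evaluate_patches`).  The default seed
    list is 0..9, i.e. the mean of ten repetitions.
    """
    per_class: dict[str, list[MetricsReport]] = {}
    for seed in seeds:
        result = run_fn(seed)
        for cls, entry in result.items():
            report = entry["report"] if isinstance(entry, dict) else entry
            per_class.setdefault(cls, []).append(report)
    return {cls: average_reports(reps) for cls, reps in per_class.items()}


def average_reports(reports: list[MetricsReport]) -> MetricsReport:
    """Mean metrics over repeated runs (NaN-aware)."""
    if not reports:
        raise InvalidInputError("no reports to average")
    with np.errstate(invalid="ignore"):
        vals = {
            k: float(np.nanmean([r.as_dict()[k] for r in reports]))
            for k in reports[0].as_dict()
        }
    undef = tuple(sorted({u for r in reports for u in r.undefined}))
    return MetricsReport(level=reports[0].level, undefined=undef, **vals)


def evaluate_segmentation(
    result: SegmentationResult,
    gt_masks: dict[str, np.ndarray],
    fov_mask: np.ndarray | None = None,
) -> dict[str, MetricsReport]:
    """Pixel-level one-vs-rest metrics per sign, within the field of view."""
    shape = result.label_map.shape
    for sign, mask in gt_masks.items():
        if mask.shape != shape:
            raise InvalidInputError("ground-truth mask shape mismatch")
    sel = np.ones(shape, dtype=bool) if fov_mask is None else fov_mask
    reports = {}
    for sign in SIGNS:
        pred = result.mask_for(sign)[sel]
        gt = gt_masks.get(sign)
        truth = np.zeros(pred.shape, dtype=bool) if gt is None else gt[sel]
        counts = ConfusionCounts(
            tp=int(np.sum(pred & truth)),
            fp=int(np.sum(pred & ~truth)),
            tn=int(np.sum(~pred & ~truth)),
            fn=int(np.sum(~pred & truth)),
        )
        reports[sign] = compute_metrics(counts, level="pixel")
    return reports


def dice_coefficient(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    pred = np.asarray(pred, bool)
    truth = np.asarray(truth, bool)
    if pred.shape != truth.shape:
        raise InvalidInputError("mask shape mismatch")
    denom = int(pred.sum()) + int(truth.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.sum(pred & truth)) / denom


__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "compute_metrics",
    "evaluate_patches",
    "evaluate_segmentation",
    "average_reports",
    "roc_points",
    "dice_coefficient",
]
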