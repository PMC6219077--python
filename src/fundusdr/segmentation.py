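"""From probability maps to mutually exclusive lesion segmentations.

The chain is: per-sign ROC-optimal threshold (Youden's J by default) ->
binarization (``p >= Th``) -> overlap resolution by probability ranking
(highest probability wins; exact ties go exudate > hemorrhage >
microaneurysm) -> per-sign morphological cleanup (closing 5x5, opening 5x5,
erosion 4x4) -> removal of every 8-connected component smaller than S^2/4
pixels (625 for S = 50).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import measure
from sklearn.metrics import roc_curve

from .errors import InvalidInputError
from .image import SIGNS
from .mapping import ProbabilityMaps

#: Integer codes of the exclusive label map.
LABEL_CODES = {"none": 0, "exudate": 1, "hemorrhage": 2, "microaneurysm": 3}

#: Structuring-element sizes of the three cleanup operations, in order.
MORPHOLOGY_PLAN = (("closing", 5), ("opening", 5), ("erosion", 4))


@dataclass
class ThresholdSet:
    """One binarization threshold per sign, with its selection record."""

    thresholds: dict[str, float]
    selection_record: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sign, th in self.thresholds.items():
            if sign not in SIGNS:
                raise InvalidInputError(f"unknown sign {sign!r}")
            if not 0 < th < 1:
                raise InvalidInputError(f"threshold for {sign} must be in (0,1), got {th}")

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"thresholds": self.thresholds, "selection_record": self.selection_record},
            indent=2,
        ))

    @classmethod
    def load(cls, path: str | Path) -> "ThresholdSet":
        data = json.loads(Path(path).read_text())
        return cls(data["thresholds"], data.get("selection_record", {}))


@dataclass
class SegmentationResult:
    """Exclusive label map plus the per-sign boolean masks derived from it."""

    label_map: np.ndarray

    @property
    def per_sign_masks(self) -> dict[str, np.ndarray]:
        return {sign: self.label_map == LABEL_CODES[sign] for sign in SIGNS}

    def mask_for(self, sign: str) -> np.ndarray:
        return self.label_map == LABEL_CODES[sign]


def select_threshold(
    scores: np.ndarray,
    truth: np.ndarray,
    criterion: str = "youden",
) -> tuple[float, dict]:
    """ROC-optimal threshold for one sign's scores against boolean truth.

    ``criterion`` is ``"youden"`` (maximize sensitivity + specificity - 1,
    the default reading of maximizing the ROC curve) or ``"closest"``
    (minimize distance to the perfect corner (0, 1)).  Candidates are the
    distinct score values; ties are broken toward the higher threshold.

    Returns ``(threshold, record)`` where the record holds the criterion
    value and the operating point.  Raises :class:`InvalidInputError` when
    the truth contains a single class.
    """
    scores = np.asarray(scores, dtype=np.float64).ravel()
    truth = np.asarray(truth, dtype=bool).ravel()
    if scores.shape != truth.shape:
        raise InvalidInputError("scores and truth must have equal length")
    if truth.all() or not truth.any():
        raise InvalidInputError("threshold selection needs both classes in the truth")
    if np.ptp(scores) == 0:
        warnings.warn("all scores identical; threshold is degenerate", stacklevel=2)
        th = float(np.clip(scores[0], 1e-6, 1 - 1e-6))
        return th, {"criterion": criterion, "value": 0.0, "degenerate": True}

    fpr, tpr, thresholds = roc_curve(truth, scores)
    # drop the sentinel point above the maximum score
    keep = np.isfinite(thresholds) & (thresholds <= scores.max())
    fpr, tpr, thresholds = fpr[keep], tpr[keep], thresholds[keep]
    if criterion == "youden":
        objective = tpr - fpr
    elif criterion == "closest":
        objective = -np.hypot(fpr, 1.0 - tpr)
    else:
        raise InvalidInputError(f"unknown criterion {criterion!r}")
    best = objective.max()
    # thresholds from roc_curve are descending: first optimum = highest Th
    i = int(np.argmax(objective >= best - 1e-15))
    th = float(np.clip(thresholds[i], 1e-9, 1 - 1e-9))
    record = {
        "criterion": criterion,
        "value": float(best if criterion == "youden" else -best),
        "sensitivity": float(tpr[i]),
        "specificity": float(1.0 - fpr[i]),
        "threshold": th,
    }
    return th, record


def fit_thresholds(
    maps_list: list[ProbabilityMaps],
    truth_masks: list[dict[str, np.ndarray]],
    fov_masks: list[np.ndarray] | None = None,
    criterion: str = "youden",
) -> ThresholdSet:
    """Per-sign thresholds fitted on held-out images (never test images).

    Scores and ground truth are pooled across the provided images, within
    the field of view when given.
    """
    if len(maps_list) != len(truth_masks):
        raise InvalidInputError("need one truth-mask dict per probability map")
    thresholds, records = {}, {}
    for sign in SIGNS:
        scores, truth = [], []
        for i, maps in enumerate(maps_list):
            sel = (
                np.ones(maps.shape, dtype=bool)
                if fov_masks is None else fov_masks[i]
            )
            scores.append(maps.sign_maps()[sign][sel])
            gt = truth_masks[i].get(sign)
            truth.append(
                np.zeros(int(sel.sum()), dtype=bool) if gt is None else gt[sel]
            )
        th, rec = select_threshold(
            np.concatenate(scores), np.concatenate(truth), criterion
        )
        thresholds[sign], records[sign] = th, rec
    return ThresholdSet(thresholds, records)


def binarize(prob_map: np.ndarray, th: float) -> np.ndarray:
    """Boolean map: pixel true iff probability >= threshold."""
    if not 0 < th < 1:
        raise InvalidInputError(f"threshold must be in (0,1), got {th}")
    return np.asarray(prob_map, dtype=np.float64) >= th


def resolve_overlaps(
    maps: ProbabilityMaps, binary_maps: dict[str, np.ndarray]
) -> np.ndarray:
    """Exclusive label map from per-sign binary maps.

    A pixel positive in one binary map keeps that sign; a pixel positive in
    several is assigned the sign with the highest probability there, exact
    ties resolved by the fixed priority exudate > hemorrhage >
    microaneurysm.
    """
    shape = maps.shape
    for sign in SIGNS:
        if binary_maps[sign].shape != shape:
            raise InvalidInputError("binary map shape does not match probability maps")
    stacked_p = np.stack([maps.sign_maps()[s] for s in SIGNS])
    stacked_b = np.stack([np.asarray(binary_maps[s], dtype=bool) for s in SIGNS])
    masked = np.where(stacked_b, stacked_p, -np.inf)
    # argmax returns the first (= highest-priority) sign among exact ties
    winner = masked.argmax(axis=0)
    label_map = np.zeros(shape, dtype=np.uint8)
    any_positive = stacked_b.any(axis=0)
    label_map[any_positive] = (winner + 1).astype(np.uint8)[any_positive]
    return label_map


def _square(n: int) -> np.ndarray:
    return np.ones((n, n), dtype=bool)


def _origin(n: int) -> tuple[int, int]:
    # Even-sized structuring elements use the top-left-of-center pixel as
    # origin; odd sizes are naturally centred.
    return (-1, -1) if n % 2 == 0 else (0, 0)


def erode(mask: np.ndarray, size: int) -> np.ndarray:
    return ndimage.binary_erosion(
        mask, structure=_square(size), origin=_origin(size), border_value=0
    )


def dilate(mask: np.ndarray, size: int) -> np.ndarray:
    origin = tuple(-o for o in _origin(size))  # adjoint of the erosion origin
    return ndimage.binary_dilation(
        mask, structure=_square(size), origin=origin, border_value=0
    )


def closing(mask: np.ndarray, size: int) -> np.ndarray:
    return erode(dilate(mask, size), size)


def opening(mask: np.ndarray, size: int) -> np.ndarray:
    return dilate(erode(mask, size), size)


def remove_small_components(mask: np.ndarray, min_area: float) -> np.ndarray:
    """Drop every 8-connected component with pixel area < ``min_area``."""
    labels = measure.label(mask, connectivity=2)
    if labels.max() == 0:
        return np.zeros_like(mask, dtype=bool)
    areas = np.bincount(labels.ravel())
    keep = np.flatnonzero(areas >= min_area)
    keep = keep[keep > 0]
    return np.isin(labels, keep)


def postprocess(binary_map: np.ndarray, patch_size: int = 50) -> np.ndarray:
    """Morphological cleanup then the S^2/4 area rule.

    Applies, in order: closing (5x5), opening (5x5), erosion (4x4), then
    removes every 8-connected component with area < ``patch_size**2 / 4``.
    """
    mask = np.asarray(binary_map, dtype=bool)
    for op_name, size in MORPHOLOGY_PLAN:
        mask = {"closing": closing, "opening": opening, "erosion": erode}[op_name](mask, size)
    return remove_small_components(mask, patch_size ** 2 / 4)


def segment_image(
    maps: ProbabilityMaps,
    thresholds: ThresholdSet,
    patch_size: int = 50,
    fov_mask: np.ndarray | None = None,
) -> SegmentationResult:
    """binarize -> resolve overlaps -> per-sign postprocess.

    The returned per-sign masks are pairwise disjoint by construction
    (post-processing only removes pixels from exclusive regions).
    """
    binary = {
        sign: binarize(maps.sign_maps()[sign], thresholds.thresholds[sign])
        for sign in SIGNS
    }
    if fov_mask is not None:
        for sign in SIGNS:
            binary[sign] &= fov_mask
    exclusive = resolve_overlaps(maps, binary)
    label_map = np.zeros(maps.shape, dtype=np.uint8)
    for sign in SIGNS:
        cleaned = postprocess(exclusive == LABEL_CODES[sign], patch_size)
        label_map[cleaned] = LABEL_CODES[sign]
    return SegmentationResult(label_map)


__all__ = [
    "ThresholdSet",
    "SegmentationResult",
    "LABEL_CODES",
    "select_threshold",
    "fit_thresholds",
    "binarize",
    "resolve_overlaps",
    "postprocess",
    "segment_image",
    "erode",
    "dilate",
    "opening",
    "closing",
    "remove_small_components",
]
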