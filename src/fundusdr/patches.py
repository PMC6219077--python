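"""Labeled S x S patch extraction, dihedral augmentation and dataset splits.

Images are tiled on a non-overlapping S-stride grid (no two patches share a
pixel).  A grid cell is labeled with a pathological sign when that sign's
ground-truth mask covers at least ``label_rule_min_overlap`` of the cell's
area; otherwise it is a no-sign (background) patch.  When two signs both
clear the bar the larger overlap wins, with exact ties resolved by the fixed
priority exudate > hemorrhage > microaneurysm.

The coverage cutoff emulates manual curation: cells that merely graze a
lesion make poor class exemplars and are better treated as background, so
the default cutoff is 10% of the cell.  A microaneurysm, however, is by
definition tiny (a few pixels across) and can never cover 10% of a 50x50
cell, so its cutoff is overridden to sit just below the smallest dot's
area; see ``label_rule_overrides``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import warnings

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, InvalidInputError
from .image import CLASSES, SIGNS, FundusImage


@dataclass(frozen=True)
class LabeledPatch:
    """One square window with its class label and provenance.

    ``origin`` is (image id, top row, left col), 0-based, for the half-open
    window ``[r, r+S) x [c, c+S)``.
    """

    window: np.ndarray
    label: str
    origin: tuple[str, int, int]

    def __post_init__(self) -> None:
        if self.label not in CLASSES:
            raise InvalidInputError(f"unknown label {self.label!r}")
        if self.window.shape[0] != self.window.shape[1]:
            raise InvalidInputError("patch window must be square")

    @property
    def size(self) -> int:
        return self.window.shape[0]


@dataclass(frozen=True)
class PatchDatasetSpec:
    """How to cut, label, augment and split a patch dataset.

    The split fractions default to (0.70, 0.15, 0.15); splitting is
    stratified by class and deterministic given ``seed``.  Augmentation
    (the 8 dihedral variants) is applied to the training split only.
    """

    patch_size: int = 50
    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0
    augment: bool = True
    label_rule_min_overlap: float = 0.10
    #: per-sign cutoff overrides; microaneurysms default to 0.004 (10 px at
    #: S=50), just below the area of the smallest 2-px-radius dot
    label_rule_overrides: tuple[tuple[str, float], ...] = (("microaneurysm", 0.004),)

    def __post_init__(self) -> None:
        if self.patch_size < 8:
            raise InvalidConfigError("patch_size must be >= 8")
        fr = self.split_fractions
        if len(fr) != 3 or any(f < 0 or f > 1 for f in fr):
            raise InvalidConfigError("split fractions must lie in [0, 1]")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise InvalidConfigError("split fractions must sum to 1")
        for frac in (self.label_rule_min_overlap,
                     *(v for _, v in self.label_rule_overrides)):
            if not 0 < frac <= 1:
                raise InvalidConfigError("label-rule cutoffs must be in (0, 1]")

    def min_overlap_for(self, sign: str) -> float:
        return dict(self.label_rule_overrides).get(sign, self.label_rule_min_overlap)


def extract_patches(image: FundusImage, spec: PatchDatasetSpec) -> list[LabeledPatch]:
    """Tile ``image`` into non-overlapping labeled S x S patches.

    Raises :class:`InvalidInputError` when the image is smaller than one
    patch.  Partial cells at the right/bottom edge are dropped, so the grid
    has ``floor(H/S) * floor(W/S)`` patches.
    """
    s = spec.patch_size
    h, w = image.shape
    if h < s or w < s:
        raise InvalidInputError(f"image {h}x{w} smaller than patch size {s}")
    min_pixels = {sign: spec.min_overlap_for(sign) * s * s for sign in SIGNS}
    patches = []
    for r in range(0, h - s + 1, s):
        for c in range(0, w - s + 1, s):
            window = image.pixels[r:r + s, c:c + s].copy()
            overlaps = {
                sign: int(mask[r:r + s, c:c + s].sum())
                for sign, mask in image.gt_masks.items()
            }
            label = "no_sign"
            best = 0
            for sign in SIGNS:  # priority order breaks exact ties
                ov = overlaps.get(sign, 0)
                if ov >= min_pixels[sign] and ov > best:
                    label, best = sign, ov
            patches.append(LabeledPatch(window, label, (image.image_id, r, c)))
    return patches


def augment(patch: LabeledPatch) -> list[LabeledPatch]:
    """The 8 dihedral-group variants of a square patch (label preserved).

    Order: identity, rot90, rot180, rot270, horizontal flip, vertical flip,
    transpose, anti-transpose.
    """
    if patch.window.shape[0] != patch.window.shape[1]:
        raise InvalidInputError("augment requires a square patch")
    w = patch.window
    variants = [
        w,
        np.rot90(w, 1),
        np.rot90(w, 2),
        np.rot90(w, 3),
        w[:, ::-1],
        w[::-1, :],
        np.rot90(w, 1)[::-1, :],   # transpose
        np.rot90(w, 3)[::-1, :],   # anti-transpose
    ]
    return [LabeledPatch(v.copy(), patch.label, patch.origin) for v in variants]


def split_dataset(
    patches: list[LabeledPatch], spec: PatchDatasetSpec
) -> tuple[list[LabeledPatch], list[LabeledPatch], list[LabeledPatch]]:
    """Stratified, seeded train/validation/test partition of patches.

    Per-class sizes follow the largest-remainder rounding of the split
    fractions so they are exact whenever the fractions are.  A class with
    fewer patches than splits goes entirely to training (with a warning).
    Augmentation, when enabled in the spec, is applied to the training split
    only.
    """
    if not patches:
        raise InvalidInputError("cannot split an empty patch list")
    rng = np.random.default_rng(spec.seed)
    train: list[LabeledPatch] = []
    val: list[LabeledPatch] = []
    test: list[LabeledPatch] = []
    for cls in CLASSES:
        members = [p for p in patches if p.label == cls]
        if not members:
            continue
        if len(members) < 3:
            warnings.warn(
                f"class {cls!r} has only {len(members)} patches; placing all in training",
                stacklevel=2,
            )
            train.extend(members)
            continue
        order = rng.permutation(len(members))
        sizes = _largest_remainder(len(members), spec.split_fractions)
        a, b = sizes[0], sizes[0] + sizes[1]
        train.extend(members[i] for i in order[:a])
        val.extend(members[i] for i in order[a:b])
        test.extend(members[i] for i in order[b:])
    if spec.augment:
        train = [v for p in train for v in augment(p)]
    return train, val, test


def _largest_remainder(n: int, fractions: tuple[float, ...]) -> list[int]:
    raw = [f * n for f in fractions]
    sizes = [int(np.floor(x)) for x in raw]
    short = n - sum(sizes)
    remainders = sorted(
        range(len(raw)), key=lambda i: raw[i] - sizes[i], reverse=True
    )
    for i in remainders[:short]:
        sizes[i] += 1
    return sizes


def save_manifest(
    patches: dict[str, list[LabeledPatch]], out_dir: str | Path
) -> pd.DataFrame:
    """Persist patches as a directory of PNG files plus a CSV manifest.

    ``patches`` maps split name -> patch list.  Windows are rounded to 8-bit
    for storage.  Returns the manifest frame (columns: path, label,
    image_id, row, col, split).
    """
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for split, plist in patches.items():
        split_dir = out_dir / split
        split_dir.mkdir(exist_ok=True)
        for i, p in enumerate(plist):
            rel = f"{split}/{i:06d}_{p.label}.png"
            arr = np.clip(np.round(p.window), 0, 255).astype(np.uint8)
            Image.fromarray(arr).save(out_dir / rel)
            rows.append(
                dict(path=rel, label=p.label, image_id=p.origin[0],
                     row=p.origin[1], col=p.origin[2], split=split)
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def load_manifest(out_dir: str | Path) -> dict[str, list[LabeledPatch]]:
    """Inverse of :func:`save_manifest` (windows come back as 8-bit floats)."""
    from PIL import Image

    out_dir = Path(out_dir)
    manifest = pd.read_csv(out_dir / "manifest.csv")
    result: dict[str, list[LabeledPatch]] = {}
    for rec in manifest.itertuples():
        window = np.asarray(Image.open(out_dir / rec.path)).astype(np.float64)
        patch = LabeledPatch(window, rec.label, (rec.image_id, rec.row, rec.col))
        result.setdefault(rec.split, []).append(patch)
    return result


__all__ = [
    "LabeledPatch",
    "PatchDatasetSpec",
    "extract_patches",
    "augment",
    "split_dataset",
    "save_manifest",
    "load_manifest",
]
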