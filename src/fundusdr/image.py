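"""Core image container for fundus photographs and their annotations.

A :class:`FundusImage` bundles the pixel grid with the optional circular
field-of-view (FOV) mask and the per-sign ground-truth lesion masks.  All
pipeline stages pass this container around so that masks are resized and
cropped together with the pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

#: Canonical ordering of the three pathological signs.  This order is also the
#: fixed tie-break priority used whenever two signs compete for a pixel or a
#: patch label (exudate > hemorrhage > microaneurysm).
SIGNS = ("exudate", "hemorrhage", "microaneurysm")

#: The four patch classes: the three signs plus background.
CLASSES = SIGNS + ("no_sign",)

#: Class name -> integer index used by the classifier.
CLASS_INDEX = {name: i for i, name in enumerate(CLASSES)}


@dataclass
class FundusImage:
    """An RGB (or single-channel) fundus image with optional annotations.

    Parameters
    ----------
    pixels
        ``H x W x 3`` or ``H x W`` float array.  Intensities follow an 8-bit
        gray convention (0-255) but stay in floating point between stages.
    fov_mask
        Optional ``H x W`` boolean circular field of view; pixels outside it
        are not part of the retina.
    gt_masks
        Optional mapping sign name -> ``H x W`` boolean lesion mask.  Masks of
        distinct signs must be pairwise disjoint.
    image_id
        Identifier used in patch provenance records and output filenames.
    """

    pixels: np.ndarray
    fov_mask: np.ndarray | None = None
    gt_masks: dict[str, np.ndarray] = field(default_factory=dict)
    image_id: str = "image"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.size == 0:
            raise InvalidInputError("image has no pixels")
        if self.pixels.ndim not in (2, 3):
            raise InvalidInputError(
                f"pixels must be HxW or HxWx3, got shape {self.pixels.shape}"
            )
        if self.pixels.ndim == 3 and self.pixels.shape[2] != 3:
            raise InvalidInputError(
                f"color images must have 3 channels, got {self.pixels.shape[2]}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise InvalidInputError("image contains non-finite pixels")
        hw = self.shape
        if self.fov_mask is not None:
            self.fov_mask = np.asarray(self.fov_mask, dtype=bool)
            if self.fov_mask.shape != hw:
                raise InvalidInputError("fov_mask shape does not match image")
        masks = {}
        for name, mask in self.gt_masks.items():
            if name not in SIGNS:
                raise InvalidInputError(f"unknown sign {name!r}")
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != hw:
                raise InvalidInputError(f"mask {name!r} shape does not match image")
            masks[name] = mask
        names = list(masks)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if np.any(masks[a] & masks[b]):
                    raise InvalidInputError(
                        f"ground-truth masks {a!r} and {b!r} overlap"
                    )
        self.gt_masks = masks

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial ``(H, W)`` of the image."""
        return self.pixels.shape[:2]

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]

    def mask_for(self, sign: str) -> np.ndarray:
        """Ground-truth mask for ``sign``; all-False when not annotated."""
        if sign in self.gt_masks:
            return self.gt_masks[sign]
        return np.zeros(self.shape, dtype=bool)

    def with_pixels(self, pixels: np.ndarray) -> "FundusImage":
        """Copy of this image carrying new pixels but the same annotations."""
        return FundusImage(
            pixels=pixels,
            fov_mask=None if self.fov_mask is None else self.fov_mask.copy(),
            gt_masks={k: v.copy() for k, v in self.gt_masks.items()},
            image_id=self.image_id,
        )
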