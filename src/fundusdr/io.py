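"""Reading and writing images, masks and configuration files."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .errors import InvalidConfigError
from .image import SIGNS, FundusImage
from .preprocessing import PreprocessConfig


def read_image(path: str | Path, image_id: str | None = None) -> FundusImage:
    """Load a PNG/TIFF/JPEG image as a float :class:`FundusImage`."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        pixels = tifffile.imread(path).astype(np.float64)
    else:
        pixels = np.asarray(Image.open(path)).astype(np.float64)
    if pixels.ndim == 3 and pixels.shape[2] == 4:  # drop alpha
        pixels = pixels[..., :3]
    return FundusImage(pixels=pixels, image_id=image_id or path.stem)


def write_image(path: str | Path, pixels: np.ndarray) -> None:
    """Write a float 0-255 array as 8-bit PNG/JPEG (or float TIFF)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, pixels.astype(np.float32))
        return
    arr = np.clip(np.round(pixels), 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(path)


def read_mask(path: str | Path) -> np.ndarray:
    """Single-channel mask PNG: nonzero = lesion."""
    arr = np.asarray(Image.open(path))
    if arr.ndim == 3:
        arr = arr[..., :3].max(axis=2)
    return arr > 0


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray((np.asarray(mask, bool) * np.uint8(255))).save(path)


def load_masks_for(image_path: Path, masks_dir: Path) -> dict[str, np.ndarray]:
    """Per-sign masks named ``<stem>_<sign>.png`` in ``masks_dir``."""
    masks = {}
    for sign in SIGNS:
        candidate = masks_dir / f"{image_path.stem}_{sign}.png"
        if candidate.exists():
            masks[sign] = read_mask(candidate)
    return masks


def write_fundus_image(image: FundusImage, out_dir: str | Path) -> None:
    """Image as PNG plus per-sign mask PNGs and FOV."""
    out_dir = Path(out_dir)
    write_image(out_dir / f"{image.image_id}.png", image.pixels)
    for sign, mask in image.gt_masks.items():
        write_mask(out_dir / f"{image.image_id}_{sign}.png", mask)
    if image.fov_mask is not None:
        write_mask(out_dir / f"{image.image_id}_fov.png", image.fov_mask)


def read_fundus_image(png_path: str | Path) -> FundusImage:
    """Inverse of :func:`write_fundus_image`."""
    png_path = Path(png_path)
    img = read_image(png_path)
    masks_dir = png_path.parent
    gt = load_masks_for(png_path, masks_dir)
    fov_path = masks_dir / f"{png_path.stem}_fov.png"
    fov = read_mask(fov_path) if fov_path.exists() else None
    return FundusImage(pixels=img.pixels, fov_mask=fov, gt_masks=gt,
                       image_id=png_path.stem)


_PREPROCESS_KEYS = {"alpha", "beta", "sigma", "mu", "clip", "per_channel", "scale_sigma"}


def load_preprocess_config(path: str | Path) -> PreprocessConfig:
    """YAML keys: alpha, beta, sigma, mu, clip, per_channel, scale_sigma."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(data) - _PREPROCESS_KEYS
    if unknown:
        raise InvalidConfigError(f"unknown preprocessing keys: {sorted(unknown)}")
    kwargs = {k: v for k, v in data.items() if k not in ("clip",)}
    if "clip" in data:
        clip = data["clip"]
        kwargs["clip_range"] = None if clip in (None, False) else tuple(clip)
    return PreprocessConfig(**kwargs)


__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "write_fundus_image",
    "read_fundus_image",
    "load_masks_for",
    "load_preprocess_config",
]
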