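"""Per-pixel probability maps from the sliding-window classifier.

For every pixel on a stride grid, the S x S window centered there (the image
is reflect-padded so border pixels have full windows) is classified and the
four softmax scores are written at that pixel, giving three sign maps
P_E, P_H, P_M plus the implicit background map.  With stride > 1 the
off-grid pixels are filled by bilinear interpolation of the grid values;
the values *at* grid pixels are exactly what per-pixel evaluation would
produce there.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.interpolate import RegularGridInterpolator

from .errors import InvalidInputError
from .image import SIGNS, FundusImage


@dataclass
class ProbabilityMaps:
    """Three per-pixel sign maps plus the implicit background map."""

    p_exudate: np.ndarray
    p_hemorrhage: np.ndarray
    p_microaneurysm: np.ndarray
    p_background: np.ndarray
    stride: int = 1

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.sign_maps().values()}
        shapes.add(self.p_background.shape)
        if len(shapes) != 1:
            raise InvalidInputError("probability maps must share one shape")

    def sign_maps(self) -> dict[str, np.ndarray]:
        """The three sign maps keyed by sign name (background excluded)."""
        return {
            "exudate": self.p_exudate,
            "hemorrhage": self.p_hemorrhage,
            "microaneurysm": self.p_microaneurysm,
        }

    @property
    def shape(self) -> tuple[int, int]:
        return self.p_exudate.shape


def extract_centered_window(
    image: FundusImage, row: int, col: int, patch_size: int
) -> np.ndarray:
    """The reflect-padded S x S window centered at ``(row, col)``.

    The window covers ``[row - S//2, row - S//2 + S)`` (same for columns),
    i.e. the pixel sits at index ``S//2`` of the window.
    """
    s = patch_size
    pad_lo, pad_hi = s // 2, s - 1 - s // 2
    pad = ((pad_lo, pad_hi), (pad_lo, pad_hi))
    if image.pixels.ndim == 3:
        pad = pad + ((0, 0),)
    padded = np.pad(image.pixels, pad, mode="reflect")
    return padded[row:row + s, col:col + s]


def generate_maps(
    model,
    image: FundusImage,
    patch_size: int | None = None,
    stride: int = 1,
    batch_size: int = 256,
) -> ProbabilityMaps:
    """Probability maps for a whole image.

    ``model`` must expose ``predict_proba(windows) -> (N, 4)`` with class
    order (exudate, hemorrhage, microaneurysm, background).  The number of
    classifier evaluations is ``ceil(H/stride) * ceil(W/stride)``.
    """
    if stride < 1:
        raise InvalidInputError(f"stride must be >= 1, got {stride}")
    s = patch_size if patch_size is not None else model.config.input_side
    h, w = image.shape
    if h < s or w < s:
        raise InvalidInputError(f"image {h}x{w} smaller than patch size {s}")

    pad_lo, pad_hi = s // 2, s - 1 - s // 2
    pad = ((pad_lo, pad_hi), (pad_lo, pad_hi))
    if image.pixels.ndim == 3:
        pad = pad + ((0, 0),)
    padded = np.pad(image.pixels, pad, mode="reflect")
    # window starting at padded[r] is centered on original pixel r
    windows = sliding_window_view(padded, (s, s), axis=(0, 1))

    rows = np.arange(0, h, stride)
    cols = np.arange(0, w, stride)
    grid = np.empty((len(rows), len(cols), 4), dtype=np.float64)
    batch_rows = max(1, batch_size // max(1, len(cols)))
    for lo in range(0, len(rows), batch_rows):
        sel = rows[lo:lo + batch_rows]
        block = windows[np.ix_(sel, cols)]  # (nr, nc, [C,] s, s)
        if block.ndim == 5:  # color: axes (nr, nc, C, s, s) -> (nr, nc, s, s, C)
            block = block.transpose(0, 1, 3, 4, 2)
        nr, nc = block.shape[:2]
        flat = block.reshape(nr * nc, s, s, -1)
        if image.pixels.ndim == 2:
            flat = flat[..., 0][..., None] * np.ones(model.config.in_channels)
        grid[lo:lo + batch_rows] = model.predict_proba(flat).reshape(nr, nc, 4)

    if stride == 1:
        full = grid
    else:
        full = _bilinear_fill(grid, rows, cols, h, w)
    return ProbabilityMaps(
        p_exudate=full[..., 0],
        p_hemorrhage=full[..., 1],
        p_microaneurysm=full[..., 2],
        p_background=full[..., 3],
        stride=stride,
    )


def _bilinear_fill(
    grid: np.ndarray, rows: np.ndarray, cols: np.ndarray, h: int, w: int
) -> np.ndarray:
    """Bilinear interpolation of grid values onto the full pixel lattice.

    Pixels beyond the last grid line take the nearest grid value (clamped
    coordinates).
    """
    interp = RegularGridInterpolator(
        (rows.astype(float), cols.astype(float)), grid, method="linear",
        bounds_error=False,
    )
    rr = np.clip(np.arange(h, dtype=float), rows[0], rows[-1])
    cc = np.clip(np.arange(w, dtype=float), cols[0], cols[-1])
    pts = np.stack(np.meshgrid(rr, cc, indexing="ij"), axis=-1)
    return interp(pts)


def save_maps(maps: ProbabilityMaps, out_dir: str | Path, patch_size: int,
              model_checksum: str = "") -> None:
    """Write one 32-bit float TIFF per sign plus a JSON sidecar."""
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for sign, arr in maps.sign_maps().items():
        tifffile.imwrite(out_dir / f"p_{sign}.tif", arr.astype(np.float32))
    tifffile.imwrite(out_dir / "p_background.tif", maps.p_background.astype(np.float32))
    sidecar = dict(stride=maps.stride, patch_size=patch_size,
                   model_checksum=model_checksum)
    (out_dir / "maps.json").write_text(json.dumps(sidecar, indent=2))


def load_maps(out_dir: str | Path) -> ProbabilityMaps:
    import tifffile

    out_dir = Path(out_dir)
    sidecar = json.loads((out_dir / "maps.json").read_text())
    arrays = {
        sign: tifffile.imread(out_dir / f"p_{sign}.tif").astype(np.float64)
        for sign in SIGNS
    }
    return ProbabilityMaps(
        p_exudate=arrays["exudate"],
        p_hemorrhage=arrays["hemorrhage"],
        p_microaneurysm=arrays["microaneurysm"],
        p_background=tifffile.imread(out_dir / "p_background.tif").astype(np.float64),
        stride=int(sidecar["stride"]),
    )


__all__ = [
    "ProbabilityMaps",
    "generate_maps",
    "extract_centered_window",
    "save_maps",
    "load_maps",
]
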