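"""Image containers, linear RGB -> XYZ conversion, and saturation flagging.

The pipeline assumes *linear* sensor data: raw RGB after black-level
correction and normalization to [0, 1] full scale, with no gamma.  A single
3x3 matrix (from the camera's color-calibration metadata) maps linear RGB to
CIE XYZ.  Negative XYZ entries can legitimately occur — the matrix has
negative off-diagonal entries — and are preserved: non-negativity is imposed
in coefficient space by the unmixing, never on the tristimulus data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "DEFAULT_CAMERA_MATRIX",
    "DEFAULT_CLIP_THRESHOLD",
    "LinearRGBImage",
    "TristimulusImage",
    "rgb_to_xyz",
    "load_image",
    "load_mask",
    "save_float_map",
    "save_display_png",
]

#: Default linear RGB -> XYZ matrix (camera DNG color-calibration metadata
#: of the reference camera).  Row-major, XYZ rows.
DEFAULT_CAMERA_MATRIX = np.array(
    [
        [1.3565, 0.3424, 0.0420],
        [0.4073, 1.0098, -0.3516],
        [0.0222, -0.2577, 1.9889],
    ]
)

#: Fraction of full scale above which a raw channel counts as saturated.
DEFAULT_CLIP_THRESHOLD = 0.99


def _check_mask(mask, shape_hw):
    if mask is None:
        return np.ones(shape_hw, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape_hw:
        raise ValueError(f"mask shape {mask.shape} does not match image {shape_hw}")
    return mask


@dataclass
class LinearRGBImage:
    """H x W x 3 linear sensor values normalized to [0, 1] full scale."""

    pixels: np.ndarray
    bit_depth_origin: int = 16
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("pixels must be H x W x 3")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixel values must be finite")
        if px.min() < 0 or px.max() > 1:
            raise ValueError("linear RGB values must lie in [0, 1]")
        self.pixels = px
        self.mask = _check_mask(self.mask, px.shape[:2])


@dataclass
class TristimulusImage:
    """Per-pixel XYZ values c(x, y) with analysis mask and saturation flags.

    ``saturated`` marks pixels where any *source* RGB channel was at or above
    the clip threshold; such pixels violate the linear radiometric model.
    """

    pixels: np.ndarray
    mask: np.ndarray | None = None
    saturated: np.ndarray | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("pixels must be H x W x 3")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixel values must be finite")
        self.pixels = px
        self.mask = _check_mask(self.mask, px.shape[:2])
        if self.saturated is None:
            self.saturated = np.zeros(px.shape[:2], dtype=bool)
        else:
            sat = np.asarray(self.saturated, dtype=bool)
            if sat.shape != px.shape[:2]:
                raise ValueError("saturated flags must match image shape")
            self.saturated = sat

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


def rgb_to_xyz(
    img: LinearRGBImage,
    matrix: np.ndarray | None = None,
    clip_threshold: float = DEFAULT_CLIP_THRESHOLD,
) -> TristimulusImage:
    """Convert linear RGB to XYZ by a per-pixel 3x3 matrix product.

    Saturation flags are set where any input channel is at or above
    ``clip_threshold``; the mask is propagated unchanged.  Negative XYZ
    outputs are preserved.
    """
    matrix = DEFAULT_CAMERA_MATRIX if matrix is None else np.asarray(matrix, float)
    if matrix.shape != (3, 3):
        raise ValueError("camera matrix must be 3x3")
    if abs(np.linalg.det(matrix)) < 1e-12:
        raise ValueError("camera matrix is singular")
    xyz = np.einsum("ij,hwj->hwi", matrix, img.pixels)
    saturated = np.any(img.pixels >= clip_threshold, axis=2)
    return TristimulusImage(xyz, mask=img.mask, saturated=saturated)


def _read_array(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        return tifffile.imread(path)
    return iio.imread(path)


def _normalize_integer(arr: np.ndarray) -> tuple[np.ndarray, int]:
    if np.issubdtype(arr.dtype, np.floating):
        return arr.astype(float), 16
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0, 8
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0, 16
    raise ValueError(f"unsupported image dtype {arr.dtype} (use uint8/uint16/float)")


def load_mask(path: str | Path) -> np.ndarray:
    """Load a single-channel mask image; nonzero pixels mean 'analyze'."""
    arr = _read_array(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr != 0


def load_image(
    path: str | Path,
    kind: str = "rgb",
    mask_path: str | Path | None = None,
) -> LinearRGBImage | TristimulusImage:
    """Load a linear image from TIFF/PNG.

    Integer images are rescaled to [0, 1] by full-scale division; no gamma is
    applied (inputs are declared linear — a gamma-encoded source is not
    detected and is the caller's responsibility).  ``kind='xyz'`` returns a
    :class:`TristimulusImage` with values taken as-is.
    """
    arr = _read_array(path)
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise ValueError("expected an H x W x 3 image")
    arr = arr[..., :3]
    mask = load_mask(mask_path) if mask_path is not None else None
    if kind == "rgb":
        px, depth = _normalize_integer(arr)
        return LinearRGBImage(px, bit_depth_origin=depth, mask=mask)
    if kind == "xyz":
        px, _ = _normalize_integer(arr)
        return TristimulusImage(px.astype(float), mask=mask)
    raise ValueError("kind must be 'rgb' or 'xyz'")


def save_float_map(path: str | Path, values: np.ndarray) -> None:
    """Write a quantitative coefficient map as 32-bit float TIFF."""
    arr = np.asarray(values, dtype=np.float32)
    kwargs = {"photometric": "rgb"} if arr.ndim == 3 and arr.shape[2] == 3 else {}
    tifffile.imwrite(str(path), arr, **kwargs)


def save_display_png(path: str | Path, values: np.ndarray) -> None:
    """Write a per-image rescaled 16-bit PNG for display.

    The rescaling is display-only; quantitative work must use the float TIFF
    written alongside (each display image gets its own transformation).
    """
    vals = np.asarray(values, dtype=float)
    lo, hi = float(vals.min()), float(vals.max())
    scaled = np.zeros_like(vals) if hi <= lo else (vals - lo) / (hi - lo)
    iio.imwrite(str(path), (scaled * 65535).astype(np.uint16))
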