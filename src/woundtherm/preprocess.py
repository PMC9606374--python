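"""Pre-processing of pseudo-colour thermal images.

The pipeline isolates the wound bed from a heterogeneous background in four
steps: vendor-logo removal, RGB-to-grey conversion, min-max normalisation and
threshold-based masking enhanced with morphology (hole filling, erosion,
largest-component selection).  Pixels outside the mask are *excluded* from all
downstream texture statistics rather than zero-filled — zero filling would
fabricate a high-contrast rim around the wound and corrupt every
co-occurrence feature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .synthetic import LUMA, colormap_lut

__all__ = [
    "GreyImage",
    "BinaryMask",
    "WoundBed",
    "MaskError",
    "load_image",
    "remove_logo",
    "rgb_to_grey",
    "normalise",
    "compute_mask",
    "extract_wound_bed",
]


class MaskError(ValueError):
    """Raised when masking yields a degenerate (empty) wound region."""


@dataclass
class GreyImage:
    """Single-channel image with values in [0, 1]."""

    values: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grey image must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grey image contains non-finite values")


@dataclass
class BinaryMask:
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def n_pixels(self) -> int:
        return int(self.values.sum())


@dataclass
class WoundBed:
    """Normalised grey image paired with the mask of analysis-eligible pixels."""

    grey: GreyImage
    mask: BinaryMask

    def __post_init__(self) -> None:
        if self.grey.values.shape != self.mask.values.shape:
            raise ValueError("grey image and mask shapes differ")
        if self.mask.n_pixels == 0:
            raise MaskError("wound-bed mask is empty")

    def eligible_values(self) -> np.ndarray:
        return self.grey.values[self.mask.values]


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG raster as an H x W x 3 uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def remove_logo(
    rgb: np.ndarray, logo_rect: tuple[int, int, int, int] | None
) -> np.ndarray:
    """Replace the vendor-logo rectangle with the median surrounding colour.

    The in-fill is the per-channel median of a 2-pixel border ring around the
    rectangle, which avoids introducing spurious texture.  A zero-area or
    ``None`` rectangle returns the image unchanged (a copy).
    """
    rgb = np.asarray(rgb)
    out = rgb.copy()
    if logo_rect is None:
        return out
    x0, y0, w, h = logo_rect
    if w == 0 or h == 0:
        return out
    H, W = rgb.shape[:2]
    if w < 0 or h < 0 or x0 < 0 or y0 < 0 or x0 + w > W or y0 + h > H:
        raise ValueError(f"logo_rect {logo_rect} outside image bounds {(W, H)}")
    ring = np.zeros((H, W), dtype=bool)
    ry0, ry1 = max(y0 - 2, 0), min(y0 + h + 2, H)
    rx0, rx1 = max(x0 - 2, 0), min(x0 + w + 2, W)
    ring[ry0:ry1, rx0:rx1] = True
    ring[y0 : y0 + h, x0 : x0 + w] = False
    if not ring.any():  # rectangle covers the whole frame
        fill = np.median(rgb.reshape(-1, rgb.shape[-1]), axis=0)
    else:
        fill = np.median(rgb[ring], axis=0)
    out[y0 : y0 + h, x0 : x0 + w] = np.round(fill).astype(rgb.dtype)
    return out


def rgb_to_grey(
    rgb: np.ndarray,
    mode: Literal["luminance", "colormap_inverse"] = "luminance",
    colormap_name: str = "ironbow",
) -> GreyImage:
    """Convert a pseudo-colour raster back to a grey field in [0, 1].

    ``luminance`` computes Rec.709 luminance (0.2126 R + 0.7152 G + 0.0722 B)
    rescaled to [0, 1]; ``colormap_inverse`` inverts a declared monotone
    colormap by nearest-neighbour lookup against its 256-entry table.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB raster")
    rgbf = rgb.astype(float)
    if mode == "luminance":
        grey = (LUMA[0] * rgbf[..., 0] + LUMA[1] * rgbf[..., 1] + LUMA[2] * rgbf[..., 2]) / 255.0
    elif mode == "colormap_inverse":
        lut = colormap_lut(colormap_name).astype(float)  # 256 x 3
        flat = rgbf.reshape(-1, 3)
        d2 = ((flat[:, None, :] - lut[None, :, :]) ** 2).sum(axis=2)
        grey = (np.argmin(d2, axis=1) / (lut.shape[0] - 1)).reshape(rgb.shape[:2])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return GreyImage(values=np.clip(grey, 0.0, 1.0))


def normalise(grey: GreyImage) -> GreyImage:
    """Min-max rescale to [0, 1]; a constant image maps to all zeros."""
    v = grey.values
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        warnings.warn(
            "constant image: normalisation returns all zeros", stacklevel=2
        )
        return GreyImage(values=np.zeros_like(v), provenance=grey.provenance)
    return GreyImage(values=(v - lo) / (hi - lo), provenance=grey.provenance)


def compute_mask(
    grey: GreyImage,
    method: Literal["otsu", "fixed"] = "otsu",
    threshold: float | None = None,
    erosion_radius: int = 2,
) -> BinaryMask:
    """Threshold the grey image and enhance the mask morphologically.

    ``grey >= t`` with ``t`` from Otsu's criterion (or the supplied value),
    then interior holes are flood-filled, the mask is eroded with a disk
    structuring element, and only the largest connected component is kept —
    one wound bed per image.
    """
    if erosion_radius < 0:
        raise ValueError("erosion_radius must be >= 0")
    v = grey.values
    if method == "otsu":
        t = float(threshold_otsu(v))
    elif method == "fixed":
        if threshold is None:
            raise ValueError("fixed method requires a threshold")
        t = float(threshold)
    else:
        raise ValueError(f"unknown method {method!r}")

    mask = v >= t
    mask = ndimage.binary_fill_holes(mask)
    if erosion_radius > 0:
        mask = ndimage.binary_erosion(mask, structure=disk(erosion_radius))
    if not mask.any():
        raise MaskError(
            "mask is empty after thresholding/erosion; use a smaller "
            "erosion_radius or a different threshold"
        )
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return BinaryMask(values=mask)


def extract_wound_bed(grey: GreyImage, mask: BinaryMask) -> WoundBed:
    """Pair the grey image with its mask; background pixels are excluded,
    not zero-filled, so co-occurrence pair counting can skip them."""
    return WoundBed(grey=grey, mask=mask)
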