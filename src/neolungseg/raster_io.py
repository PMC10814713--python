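"""Raster input/output for the segmentation pipeline.

Images are held in memory as plain :class:`numpy.ndarray` objects:

* a *gray image* is a 2-D ``uint8`` array of intensities in [0, 255];
* a *binary image* (mask) is a 2-D ``uint8``/``bool`` array with values {0, 1};
* an *overlay* is an M×N×3 ``uint8`` RGB array.

Color inputs are reduced to one channel with the ITU-R BT.601 luma weights
(0.299, 0.587, 0.114), rounded half-up.  Masks are written as 8-bit PNG with
{0, 255} so that a read-back followed by ``> 127`` thresholding reproduces the
mask bit-exactly.  JPEG is accepted for input only; all outputs are lossless
PNG.
"""

from __future__ import annotations

import os

import numpy as np
from PIL import Image, UnidentifiedImageError

__all__ = [
    "read_gray",
    "read_mask",
    "write_mask",
    "write_overlay",
    "as_gray",
    "as_binary",
]

# BT.601 luma weights for RGB -> gray reduction
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


def as_gray(arr: np.ndarray) -> np.ndarray:
    """Validate *arr* as a gray image and return it as a ``uint8`` array."""
    a = np.asarray(arr)
    if a.ndim != 2 or a.size == 0:
        raise ValueError(f"gray image must be a non-empty 2-D array, got shape {a.shape}")
    if np.issubdtype(a.dtype, np.floating):
        if not np.allclose(a, np.round(a)):
            raise ValueError("gray image intensities must be integers")
        a = np.round(a)
    if a.min() < 0 or a.max() > 255:
        raise ValueError("gray image intensities must lie in [0, 255]")
    return a.astype(np.uint8)


def as_binary(arr: np.ndarray) -> np.ndarray:
    """Validate *arr* as a binary image and return it as a ``uint8`` {0,1} array."""
    a = np.asarray(arr)
    if a.ndim != 2 or a.size == 0:
        raise ValueError(f"binary image must be a non-empty 2-D array, got shape {a.shape}")
    if a.dtype == bool:
        return a.astype(np.uint8)
    vals = np.unique(a)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("binary image values must be exactly 0 or 1")
    return a.astype(np.uint8)


def read_gray(path: str | os.PathLike) -> np.ndarray:
    """Read a JPEG/PNG raster and return it as an M×N ``uint8`` gray image.

    Multi-channel inputs are reduced with the BT.601 luma transform
    (0.299 R + 0.587 G + 0.114 B), rounded half-up; single-channel inputs
    pass through unchanged.  An alpha channel, if present, is ignored.
    """
    try:
        with Image.open(path) as im:
            im.load()
            if im.mode in ("1", "I", "I;16", "F"):
                im = im.convert("L")
            arr = np.asarray(im)
    except FileNotFoundError:
        raise
    except (UnidentifiedImageError, OSError) as exc:
        raise OSError(f"cannot decode image file: {path}") from exc
    if arr.size == 0:
        raise ValueError(f"zero-sized image: {path}")
    if arr.ndim == 2:
        return arr.astype(np.uint8)
    if arr.ndim == 3:
        rgb = arr[..., :3].astype(np.float64)
        # round half-up so e.g. pure red gives round(0.299*255) = 76
        gray = np.floor(rgb @ _LUMA_WEIGHTS + 0.5)
        return np.clip(gray, 0, 255).astype(np.uint8)
    raise ValueError(f"unsupported image layout with shape {arr.shape}: {path}")


def read_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a mask PNG: gray-load then threshold at > 127 to {0, 1}."""
    return (read_gray(path) > 127).astype(np.uint8)


def _require_png(path: str | os.PathLike) -> None:
    if not str(path).lower().endswith(".png"):
        raise ValueError(f"lossless PNG output required, got: {path}")


def write_mask(mask: np.ndarray, path: str | os.PathLike) -> None:
    """Write a binary mask as an 8-bit PNG with 0 -> 0 and 1 -> 255."""
    _require_png(path)
    m = as_binary(mask)
    Image.fromarray(m * np.uint8(255), mode="L").save(path, format="PNG")


def write_overlay(overlay: np.ndarray, path: str | os.PathLike) -> None:
    """Write an M×N×3 RGB overlay as a PNG (lossless, bit-exact round-trip)."""
    _require_png(path)
    a = np.asarray(overlay)
    if a.ndim != 3 or a.shape[2] != 3 or a.size == 0:
        raise ValueError(f"overlay must be a non-empty M×N×3 array, got shape {a.shape}")
    if a.min() < 0 or a.max() > 255:
        raise ValueError("overlay channel values must lie in [0, 255]")
    Image.fromarray(a.astype(np.uint8), mode="RGB").save(path, format="PNG")
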