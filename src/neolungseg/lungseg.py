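"""Rule-based lung-field segmentation for neonatal chest radiographs.

The pipeline turns a grayscale anteroposterior chest film into a binary lung
mask plus a colored overlay, in six fixed stages:

1. **binarize** — global threshold ``T`` (Otsu by default).  Aerated lung is
   radiolucent (dark), so the default polarity selects pixels with intensity
   ``<= T``; the literal bright-foreground convention (``> T``) is available
   via ``invert_polarity=False``.
2. **dilate** — binary dilation with a small structuring element to
   strengthen contours and bridge one- or two-pixel interruptions.
3. **remove_small** — connected components with area ``<= U`` pixels are
   discarded as noise (note the *inclusive* bound: a component of area
   exactly ``U`` is removed).
4. **ROI mask** — the pulmonary region of interest ``Q``: by default the
   union of the ``k`` largest remaining components (one per lung, ``k=2``),
   or an externally supplied mask file.
5. **close** — morphological closing (dilation then erosion, zero-padded)
   with a larger element fills gaps and joins interrupted contours; the
   result is re-intersected with ``Q`` so the closing cannot leak past the
   ROI boundary.
6. **overlay** — the masked radiograph (elementwise product of image and
   mask) and an RGB rendering with the lung field alpha-blended in color.

All stage rasters are retained in the returned :class:`SegResult` so that
intermediate behavior can be inspected and tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import ndimage

from .raster_io import as_binary, as_gray, read_mask

__all__ = [
    "StructuringElement",
    "SegConfig",
    "SegResult",
    "binarize",
    "otsu_threshold",
    "dilate",
    "remove_small",
    "make_roi_mask",
    "apply_mask",
    "close_mask",
    "overlay",
    "segment",
]

logger = logging.getLogger("neolungseg.lungseg")


# ---------------------------------------------------------------------------
# structuring elements
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StructuringElement:
    """A binary morphology footprint centred on its origin.

    Parameters
    ----------
    shape
        ``"disk"`` (Euclidean ball), ``"square"`` (side ``2r+1``) or
        ``"cross"`` (centre row and column of a ``2r+1`` square).
    radius
        Positive integer radius.
    """

    shape: Literal["disk", "square", "cross"] = "disk"
    radius: int = 1

    def __post_init__(self) -> None:
        if self.shape not in ("disk", "square", "cross"):
            raise ValueError(f"unknown structuring element shape: {self.shape!r}")
        if int(self.radius) < 1 or self.radius != int(self.radius):
            raise ValueError(f"structuring element radius must be a positive integer, got {self.radius}")

    def footprint(self) -> np.ndarray:
        """Return the (2r+1)×(2r+1) binary footprint; the origin is always set."""
        r = int(self.radius)
        if self.shape == "square":
            return np.ones((2 * r + 1, 2 * r + 1), dtype=bool)
        yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
        if self.shape == "disk":
            return (yy * yy + xx * xx) <= r * r
        fp = np.zeros((2 * r + 1, 2 * r + 1), dtype=bool)
        fp[r, :] = True
        fp[:, r] = True
        return fp


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegConfig:
    """Pipeline parameters.

    Defaults encode the standard operating point: Otsu threshold, dark
    (radiolucent) foreground, disk(3) dilation, area floor of 0.1% of the
    frame, two-component auto ROI, disk(7) closing, red overlay at blend
    weight 0.5, 8-connectivity.
    """

    threshold_mode: Literal["otsu", "fixed"] = "otsu"
    threshold_value: int = 128
    invert_polarity: bool = True
    dilation_se: StructuringElement = field(default_factory=lambda: StructuringElement("disk", 3))
    closing_se: StructuringElement = field(default_factory=lambda: StructuringElement("disk", 7))
    #: component-area floor in pixels; None means 0.1% of the image area
    area_threshold: Optional[int] = None
    roi_policy: Literal["auto_largest_k", "external_file"] = "auto_largest_k"
    roi_k: int = 2
    roi_path: Optional[str] = None
    overlay_color: tuple[int, int, int] = (255, 0, 0)
    connectivity: Literal[4, 8] = 8

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("otsu", "fixed"):
            raise ValueError(f"unknown threshold_mode: {self.threshold_mode!r}")
        if not 0 <= self.threshold_value <= 255:
            raise ValueError("threshold_value must lie in [0, 255]")
        if self.area_threshold is not None and self.area_threshold < 0:
            raise ValueError("area_threshold must be >= 0")
        if self.roi_policy not in ("auto_largest_k", "external_file"):
            raise ValueError(f"unknown roi_policy: {self.roi_policy!r}")
        if self.roi_k < 1:
            raise ValueError("roi_k must be >= 1")
        if self.roi_policy == "external_file" and not self.roi_path:
            raise ValueError("roi_policy='external_file' requires roi_path")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if len(self.overlay_color) != 3 or not all(0 <= c <= 255 for c in self.overlay_color):
            raise ValueError("overlay_color must be an RGB triple in [0, 255]")

    def resolved_area_threshold(self, shape: tuple[int, int]) -> int:
        if self.area_threshold is not None:
            return int(self.area_threshold)
        return int(round(0.001 * shape[0] * shape[1]))


@dataclass(frozen=True)
class SegResult:
    """All stage rasters of one segmentation run."""

    binary: np.ndarray
    dilated: np.ndarray
    cleaned: np.ndarray
    roi: np.ndarray
    masked: np.ndarray
    closed: np.ndarray
    overlay: np.ndarray
    threshold_used: int

    def stage_counts(self) -> dict[str, int]:
        """Foreground pixel count per stage, in pipeline order."""
        return {
            "binary": int(self.binary.sum()),
            "dilated": int(self.dilated.sum()),
            "cleaned": int(self.cleaned.sum()),
            "roi": int(self.roi.sum()),
            "masked": int(self.masked.sum()),
            "closed": int(self.closed.sum()),
        }


# ---------------------------------------------------------------------------
# stage operations
# ---------------------------------------------------------------------------

def binarize(image: np.ndarray, threshold: float, invert: bool = False) -> np.ndarray:
    """Global threshold.

    With ``invert=False`` the foreground is the bright side, strictly
    ``image > threshold``; with ``invert=True`` it is the complementary dark
    side, ``image <= threshold``.
    """
    x = as_gray(image)
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    if invert:
        return (x <= threshold).astype(np.uint8)
    return (x > threshold).astype(np.uint8)


def otsu_threshold(image: np.ndarray) -> int:
    """Otsu's threshold on the 256-bin histogram of an 8-bit image.

    Returns the integer ``T`` maximising the between-class variance of the
    split ``{<= T} / {> T}``; ties are broken by the smallest qualifying
    ``T``.  A constant image has no defined threshold and raises
    ``ValueError``.
    """
    x = as_gray(image)
    hist = np.bincount(x.ravel(), minlength=256).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        raise ValueError("Otsu threshold is undefined for a constant image")
    p = hist / hist.sum()
    levels = np.arange(256, dtype=np.float64)
    omega = np.cumsum(p)                      # class-0 probability for T = 0..255
    mu = np.cumsum(p * levels)                # first moment up to T
    mu_total = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_total * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -1.0     # degenerate splits never win
    return int(np.argmax(sigma_b))            # argmax returns the smallest tie


def dilate(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Binary dilation with zero padding outside the frame."""
    m = as_binary(mask)
    out = ndimage.binary_dilation(m.astype(bool), structure=se.footprint(), border_value=0)
    return out.astype(np.uint8)


def erode(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Binary erosion with zero padding outside the frame."""
    m = as_binary(mask)
    out = ndimage.binary_erosion(m.astype(bool), structure=se.footprint(), border_value=0)
    return out.astype(np.uint8)


def _label(mask: np.ndarray, connectivity: int) -> tuple[np.ndarray, int]:
    structure = ndimage.generate_binary_structure(2, 1 if connectivity == 4 else 2)
    return ndimage.label(mask, structure=structure)


def remove_small(mask: np.ndarray, area_threshold: int, connectivity: int = 8) -> np.ndarray:
    """Drop connected components whose area is ``<= area_threshold`` pixels."""
    m = as_binary(mask)
    if area_threshold < 0:
        raise ValueError("area_threshold must be >= 0")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    if area_threshold == 0 or not m.any():
        return m.copy()
    labels, n = _label(m, connectivity)
    if n == 0:
        return m.copy()
    areas = np.bincount(labels.ravel())[1:]   # per-label component areas
    keep = np.flatnonzero(areas > area_threshold) + 1
    return np.isin(labels, keep).astype(np.uint8)


def make_roi_mask(mask: np.ndarray, config: SegConfig) -> np.ndarray:
    """Build the pulmonary region-of-interest mask ``Q``.

    Under the auto policy, ``Q`` is the union of the ``roi_k`` largest
    connected components of *mask* (area ties broken by the smaller label in
    row-major labeling order).  Under the external-file policy, ``Q`` is read
    from ``config.roi_path`` and must match the mask's dimensions.
    """
    m = as_binary(mask)
    if config.roi_policy == "external_file":
        q = read_mask(config.roi_path)
        if q.shape != m.shape:
            raise ValueError(
                f"external ROI mask shape {q.shape} does not match image shape {m.shape}"
            )
        return q
    if not m.any():
        raise ValueError("no candidate region: mask is empty under auto ROI policy")
    labels, n = _label(m, config.connectivity)
    areas = np.bincount(labels.ravel())[1:]
    # stable sort by descending area keeps smaller label index on ties
    order = np.argsort(-areas, kind="stable")[: config.roi_k] + 1
    return np.isin(labels, order).astype(np.uint8)


def apply_mask(mask: np.ndarray, roi: np.ndarray) -> np.ndarray:
    """Elementwise product (logical AND) of a binary image with the ROI mask."""
    m = as_binary(mask)
    q = as_binary(roi)
    if m.shape != q.shape:
        raise ValueError(f"shape mismatch: {m.shape} vs {q.shape}")
    return (m & q).astype(np.uint8)


def close_mask(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Morphological closing: dilation then erosion, both zero-padded.

    Fills gaps and connects interrupted contours.  With zero padding the
    erosion can nibble foreground lying within one radius of the frame
    border; lungs on AP films keep clear of the border, so this does not
    arise in practice.
    """
    return erode(dilate(mask, se), se)


def overlay(image: np.ndarray, mask: np.ndarray, color: Sequence[int] = (255, 0, 0)) -> np.ndarray:
    """Render the radiograph in gray with the mask alpha-blended in *color*.

    Inside the mask each channel is ``round(0.5*gray + 0.5*color_c)``
    (half-up); outside, the grayscale value is replicated on all three
    channels.
    """
    x = as_gray(image)
    m = as_binary(mask)
    if x.shape != m.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {m.shape}")
    rgb = np.repeat(x[..., None], 3, axis=2).astype(np.float64)
    col = np.asarray(color, dtype=np.float64)
    blended = np.floor(0.5 * rgb + 0.5 * col + 0.5)
    out = np.where(m[..., None].astype(bool), blended, rgb)
    return out.astype(np.uint8)


def masked_product(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Elementwise product of the radiograph with a binary mask (the
    visualization image: original intensities inside the mask, 0 outside)."""
    x = as_gray(image)
    m = as_binary(mask)
    if x.shape != m.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {m.shape}")
    return (x * m).astype(np.uint8)


# ---------------------------------------------------------------------------
# composed pipeline
# ---------------------------------------------------------------------------

def segment(image: np.ndarray, config: SegConfig | None = None) -> SegResult:
    """Run the full stage chain on a grayscale radiograph.

    Emits one structured log line per stage (stage name, foreground pixel
    count) at INFO level.  A constant image under Otsu mode raises
    ``ValueError``; an empty post-cleaning mask under the auto ROI policy
    yields an all-empty result rather than an error.
    """
    cfg = config or SegConfig()
    x = as_gray(image)

    if cfg.threshold_mode == "otsu":
        t = otsu_threshold(x)
    else:
        t = int(cfg.threshold_value)

    binary = binarize(x, t, invert=cfg.invert_polarity)
    logger.info("stage=binarize threshold=%d foreground=%d", t, int(binary.sum()))

    dilated = dilate(binary, cfg.dilation_se)
    logger.info("stage=dilate foreground=%d", int(dilated.sum()))

    u = cfg.resolved_area_threshold(x.shape)
    cleaned = remove_small(dilated, u, cfg.connectivity)
    logger.info("stage=remove_small area_threshold=%d foreground=%d", u, int(cleaned.sum()))

    if cfg.roi_policy == "auto_largest_k" and not cleaned.any():
        # nothing survived cleaning: empty result at every downstream stage
        empty = np.zeros_like(cleaned)
        logger.info("stage=roi foreground=0 (no candidate components)")
        return SegResult(binary, dilated, cleaned, empty, empty, empty,
                         overlay(x, empty, cfg.overlay_color), t)

    roi = make_roi_mask(cleaned, cfg)
    logger.info("stage=roi foreground=%d", int(roi.sum()))

    masked = apply_mask(cleaned, roi)
    logger.info("stage=apply_mask foreground=%d", int(masked.sum()))

    closed = apply_mask(close_mask(masked, cfg.closing_se), roi)
    logger.info("stage=close foreground=%d", int(closed.sum()))

    ovl = overlay(x, closed, cfg.overlay_color)
    return SegResult(binary, dilated, cleaned, roi, masked, closed, ovl, t)
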