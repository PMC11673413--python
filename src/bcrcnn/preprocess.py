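"""Image preprocessing: background-noise subtraction, short-side rescaling,
and breast-mask application.

The background level of an MRI-like slice is estimated as the mean of the
top-left 4x4 pixel block (air outside the patient), subtracted everywhere
and clamped at zero.  Slices are then rescaled so the shorter spatial side
equals a target length (512 by default) with bilinear interpolation, and a
breast mask — supplied by any segmentation model, or the built-in Otsu
baseline — zeroes out everything outside the breast.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology, transform

from .dataset_io import Plane

log = logging.getLogger("bcrcnn")


@dataclass
class RawImage:
    """A 2D grayscale slice with non-negative finite intensities."""

    pixels: np.ndarray
    plane: Plane = Plane.AXIAL

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("RawImage requires a 2D array")
        if self.pixels.shape[0] < 4 or self.pixels.shape[1] < 4:
            raise ValueError("RawImage must be at least 4x4")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("RawImage intensities must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class BackgroundEstimate:
    value: float
    block_rows: int = 4
    block_cols: int = 4

    def __post_init__(self):
        if self.value < 0:
            raise ValueError("background estimate must be non-negative")


def estimate_background(image: RawImage, N: int = 4, M: int = 4) -> BackgroundEstimate:
    """Mean intensity of the top-left N x M pixel block (default 4x4)."""
    h, w = image.shape
    if h < N or w < M:
        raise ValueError(f"image {h}x{w} smaller than background block {N}x{M}")
    value = float(image.pixels[:N, :M].mean())
    return BackgroundEstimate(value=max(value, 0.0), block_rows=N, block_cols=M)


def subtract_background(image: RawImage, bg: BackgroundEstimate) -> RawImage:
    """Subtract the constant background level, clamping negatives to zero."""
    return RawImage(np.maximum(image.pixels - bg.value, 0.0), image.plane)


def rescale_to_short_side(image: RawImage, target: int = 512) -> tuple[RawImage, float]:
    """Rescale so min(height, width) == target; returns (image, scale).

    Output dimensions are round-half-away-from-zero of dim*scale; bilinear
    resampling.  The returned scale maps source boxes into the output frame.
    """
    if target < 1:
        raise ValueError("target must be >= 1")
    h, w = image.shape
    if h == 0 or w == 0:
        raise ValueError("degenerate image")
    scale = target / min(h, w)
    out_h = int(np.floor(h * scale + 0.5))
    out_w = int(np.floor(w * scale + 0.5))
    if (out_h, out_w) == (h, w):
        return RawImage(image.pixels.copy(), image.plane), scale
    resized = transform.resize(image.pixels, (out_h, out_w), order=1,
                               mode="edge", anti_aliasing=scale < 1.0,
                               preserve_range=True)
    return RawImage(np.maximum(resized, 0.0), image.plane), scale


def rescale_mask(mask: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour mask resize to `shape`."""
    out = transform.resize(mask.astype(np.float64), shape, order=0,
                           mode="edge", anti_aliasing=False, preserve_range=True)
    return out > 0.5


def apply_breast_mask(image: RawImage, mask: np.ndarray) -> RawImage:
    """Zero every pixel outside the binary mask."""
    mask = np.asarray(mask)
    if mask.shape != image.shape:
        raise ValueError(f"mask shape {mask.shape} != image shape {image.shape}")
    return RawImage(image.pixels * (mask > 0), image.plane)


def baseline_breast_mask(image: RawImage) -> np.ndarray:
    """Threshold-based breast mask: Otsu -> largest component -> closing.

    A stand-in segmentation provider for background-subtracted slices:
    deterministic, and adequate for bright-foreground phantoms.  Returns an
    all-zero mask (with a warning) when no foreground survives.
    """
    px = image.pixels
    if px.max() <= 0:
        log.warning("baseline_breast_mask: empty foreground")
        return np.zeros(image.shape, dtype=bool)
    thr = filters.threshold_otsu(px)
    fg = px > thr
    if not fg.any():
        log.warning("baseline_breast_mask: empty foreground after threshold")
        return np.zeros(image.shape, dtype=bool)
    # a pure-noise image yields only scattered specks above threshold;
    # test coherence on the raw mask, before closing can inflate specks
    raw_labels = measure.label(fg, connectivity=2)
    raw_counts = np.bincount(raw_labels.ravel())
    raw_counts[0] = 0
    if raw_counts.max() < 0.05 * px.size:
        log.warning("baseline_breast_mask: no coherent foreground (noise only)")
        return np.zeros(image.shape, dtype=bool)
    # closing bridges the narrow gap between the two breasts of an axial
    # slice so the foreground becomes one component
    fg = morphology.closing(fg, morphology.disk(3))
    labels = measure.label(fg, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    mask = labels == counts.argmax()
    return ndimage.binary_fill_holes(mask)


def preprocess_image(image: RawImage, target: int | None = 512,
                     mask: np.ndarray | None = None, use_mask: bool = True,
                     ) -> tuple[RawImage, float, float]:
    """Full chain: subtract background -> mask -> rescale.

    Returns (processed image, scale, background value).  `mask` overrides
    the baseline provider; `use_mask=False` skips masking entirely;
    `target=None` skips rescaling.
    """
    bg = estimate_background(image)
    out = subtract_background(image, bg)
    if use_mask:
        m = mask if mask is not None else baseline_breast_mask(out)
        out = apply_breast_mask(out, m)
    scale = 1.0
    if target is not None:
        out, scale = rescale_to_short_side(out, target)
    return out, scale, bg.value
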