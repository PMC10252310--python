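"""Foreground/background segmentation of spice-thread images.

The pipeline mirrors classic thresholding practice for dark objects on a
bright dish: Otsu's method on the green channel, selection of the darker
side as foreground, removal of small connected components, and one pass of
binary erosion with a 3x3 cross element.  Masks are plain boolean arrays of
the image geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


class EmptyForegroundError(ValueError):
    """Raised when cleanup leaves no foreground (likely a background-only image)."""


@dataclass(frozen=True)
class OtsuResult:
    """Threshold level plus a flag for degenerate (single-level) histograms."""

    level: int
    degenerate: bool = False

    def __int__(self) -> int:  # allow use directly as a level
        return self.level


#: 3x3 cross structuring element used by the single erosion pass
CROSS = ndimage.generate_binary_structure(2, 1)


def otsu_threshold(histogram: np.ndarray) -> OtsuResult:
    """Otsu threshold of a 256-bin histogram.

    Returns the level ``t`` maximising the between-class variance of the two
    groups ``{<= t}`` and ``{> t}``; ties break toward the lower level.  A
    histogram with all mass in one bin is degenerate: that bin's level is
    returned with ``degenerate=True``.
    """
    counts = np.asarray(histogram, dtype=np.float64)
    if counts.ndim != 1 or counts.size != 256:
        raise ValueError("histogram must be a 256-bin vector")
    if np.any(counts < 0) or counts.sum() <= 0:
        raise ValueError("histogram must have nonnegative counts and >=1 nonzero bin")

    nonzero = np.flatnonzero(counts)
    if nonzero.size == 1:
        return OtsuResult(level=int(nonzero[0]), degenerate=True)

    total = counts.sum()
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(counts)[:-1]            # mass of {<= t} for t = 0..254
    w1 = total - w0
    m0 = np.cumsum(counts * levels)[:-1]
    mu0 = np.divide(m0, w0, out=np.zeros_like(m0), where=w0 > 0)
    mu1 = np.divide(counts @ levels - m0, w1, out=np.zeros_like(m0), where=w1 > 0)
    sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    return OtsuResult(level=int(np.argmax(sigma_b)), degenerate=False)


def clean_mask(mask: np.ndarray, min_area: int = 25, erode: bool = True) -> np.ndarray:
    """Remove components smaller than ``min_area`` (8-connectivity), then
    optionally apply one binary erosion pass with the 3x3 cross element."""
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=bool))
    if n:
        areas = np.bincount(labels.ravel())
        keep = areas >= min_area
        keep[0] = False
        cleaned = keep[labels]
    else:
        cleaned = mask.copy()
    if erode:
        cleaned = ndimage.binary_erosion(cleaned, structure=CROSS)
    return cleaned


def segment(image: np.ndarray, min_area: int = 25, erode: bool = True) -> np.ndarray:
    """Segment thread foreground from a bright background.

    Thresholds the green channel with :func:`otsu_threshold`, keeps the darker
    side (threads are darker than the dish), filters small components and
    erodes once.  Raises :class:`EmptyForegroundError` if nothing survives.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError("expected an RGB image of shape (H, W, 3)")
    green = image[..., 1]
    hist = np.bincount(np.clip(green, 0, 255).astype(np.int64).ravel(), minlength=256)
    result = otsu_threshold(hist[:256])
    if result.degenerate:
        raise EmptyForegroundError(
            "constant green channel: image appears to contain background only")
    raw = green <= result.level
    mask = clean_mask(raw, min_area=min_area, erode=erode)
    if not mask.any():
        raise EmptyForegroundError(
            "no foreground left after cleanup: likely a background-only image")
    return mask


def apply_mask(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero the background: output pixel = input where mask is set, else 0."""
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if image.shape[:2] != mask.shape:
        raise ValueError(
            f"geometry mismatch: image {image.shape[:2]} vs mask {mask.shape}")
    out = image.copy()
    if image.ndim == 3:
        out[~mask] = 0
    else:
        out[~mask] = 0
    return out
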