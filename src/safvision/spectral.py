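"""Two-band (red 650 nm / NIR 850 nm) reflectance calibration and features.

Raw frames are flat-field calibrated against a 100%-reflectance reference
surface and a dark frame, ``R = (sample − dark) / (reference − dark)``,
which cancels the illumination pattern and any global gain.  Per band the
mean, population standard deviation and skewness of the calibrated ROI
reflectance form a 6-element spectral feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .segmentation import clean_mask, otsu_threshold


class Band(str, Enum):
    RED = "red_650nm"
    NIR = "nir_850nm"


class FrameRole(str, Enum):
    SAMPLE = "sample"
    REFERENCE = "reference"
    DARK = "dark"


class CalibrationError(ValueError):
    """Raised when calibration is impossible (band mismatch, flat denominator)."""


@dataclass
class BandImage:
    """Single-band raster with its wavelength band and acquisition role."""

    pixels: np.ndarray
    band: Band
    role: FrameRole = FrameRole.SAMPLE

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        self.band = Band(self.band)
        self.role = FrameRole(self.role)
        if self.pixels.ndim != 2:
            raise ValueError("BandImage expects a 2-D array")
        if np.any(self.pixels < 0):
            raise ValueError("band intensities must be nonnegative")


@dataclass
class SpectralFrameSet:
    """The six frames needed to calibrate one specimen in both bands."""

    red_raw: BandImage
    nir_raw: BandImage
    reference_red: BandImage
    reference_nir: BandImage
    dark_red: BandImage
    dark_nir: BandImage

    def __post_init__(self) -> None:
        shapes = {f.pixels.shape for f in (
            self.red_raw, self.nir_raw, self.reference_red, self.reference_nir,
            self.dark_red, self.dark_nir)}
        if len(shapes) != 1:
            raise ValueError(f"all six frames must share geometry, got {shapes}")


@dataclass
class ReflectanceImage:
    """Calibrated reflectance plus a validity mask for flat-denominator pixels."""

    pixels: np.ndarray
    band: Band
    valid: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones_like(self.pixels, dtype=bool)


SPECTRAL_FEATURE_NAMES: tuple[str, ...] = (
    "mean_red", "std_red", "skew_red", "mean_nir", "std_nir", "skew_nir",
)


def calibrate(sample: BandImage, reference: BandImage,
              dark: BandImage) -> ReflectanceImage:
    """Flat-field calibration ``(sample − dark) / (reference − dark)``.

    Pixels where reference equals dark are flagged invalid and excluded from
    downstream statistics; more than 50% invalid pixels is a calibration
    failure.
    """
    if not (sample.band == reference.band == dark.band):
        raise CalibrationError(
            f"band mismatch: {sample.band}, {reference.band}, {dark.band}")
    if sample.pixels.shape != reference.pixels.shape != dark.pixels.shape:
        raise CalibrationError("frame geometry mismatch")
    den = reference.pixels - dark.pixels
    valid = den != 0
    if valid.mean() <= 0.5:
        raise CalibrationError(
            "reference and dark frames coincide on a majority of pixels")
    out = np.zeros_like(den)
    np.divide(sample.pixels - dark.pixels, den, out=out, where=valid)
    return ReflectanceImage(pixels=out, band=sample.band, valid=valid)


def spectral_stats(reflectance: ReflectanceImage,
                   mask: np.ndarray) -> tuple[float, float, float]:
    """Mean, population std and population skewness over the valid ROI.

    Skewness is the third central moment over std cubed; defined as 0 when
    the std vanishes.
    """
    mask = np.asarray(mask, dtype=bool)
    effective = mask & reflectance.valid
    if not effective.any():
        raise ValueError("empty effective ROI (mask has no valid pixels)")
    vals = reflectance.pixels[effective]
    mean = float(vals.mean())
    std = float(vals.std())
    # float round-off on a constant region leaves std ~ 1e-16; the skewness
    # of that noise is meaningless, so treat it as exactly constant
    if std <= 1e-12 * max(1.0, abs(mean)):
        return mean, std, 0.0
    skew = float(np.mean((vals - mean) ** 3) / std ** 3)
    return mean, std, skew


def segment_spectral(frames: SpectralFrameSet, min_area: int = 10,
                     erode: bool = True) -> np.ndarray:
    """Threshold the calibrated NIR band (Otsu), keeping the brighter side.

    Threads reflect more NIR than the dish surface in this rig, so the
    foreground is the high-reflectance side of the cut.
    """
    refl = calibrate(frames.nir_raw, frames.reference_nir, frames.dark_nir)
    vals = refl.pixels[refl.valid]
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:
        raise ValueError("constant calibrated NIR frame; cannot segment")
    quant = np.clip(np.rint((refl.pixels - lo) / (hi - lo) * 255), 0, 255)
    hist = np.bincount(quant[refl.valid].astype(np.int64).ravel(), minlength=256)
    level = otsu_threshold(hist[:256]).level
    mask = (quant > level) & refl.valid
    return clean_mask(mask, min_area=min_area, erode=erode)


def extract_spectral_features(frames: SpectralFrameSet,
                              mask: np.ndarray | None = None) -> pd.Series:
    """Calibrate both bands and return the 6-element spectral feature vector.

    If no mask is given the frames are segmented with :func:`segment_spectral`.
    """
    if mask is None:
        mask = segment_spectral(frames)
    red = calibrate(frames.red_raw, frames.reference_red, frames.dark_red)
    nir = calibrate(frames.nir_raw, frames.reference_nir, frames.dark_nir)
    if red.band != Band.RED or nir.band != Band.NIR:
        raise CalibrationError("frame set has swapped or mislabelled bands")
    values = [*spectral_stats(red, mask), *spectral_stats(nir, mask)]
    return pd.Series(values, index=list(SPECTRAL_FEATURE_NAMES), dtype=np.float64)
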