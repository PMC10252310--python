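"""ROI color and texture features for RGB thread images.

Eighteen color features (mean and population standard deviation of R, G, B,
H, S, I, L*, a*, b* over the segmented region) plus three first-order
histogram texture measures — smoothness, uniformity and entropy — computed
on the 256-level gray histogram of the ROI intensity.  Together they form
the fixed 21-element feature vector consumed by the classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .color import to_hsi, to_lab

#: fixed feature order of the 21-element vector
FEATURE_NAMES: tuple[str, ...] = (
    "r_ave", "r_std", "g_ave", "g_std", "b_ave", "b_std",
    "h_ave", "h_std", "s_ave", "s_std", "i_ave", "i_std",
    "l_ave", "l_std", "a_ave", "a_std", "bstar_ave", "bstar_std",
    "smoothness", "uniformity", "entropy",
)

COLOR_FEATURE_NAMES: tuple[str, ...] = FEATURE_NAMES[:18]
TEXTURE_FEATURE_NAMES: tuple[str, ...] = FEATURE_NAMES[18:]

#: the reduced 14-feature set; the duplicated printed name "b_ave" is resolved
#: as blue-channel mean first, b* mean second (configurable by callers that
#: build their own group)
SELECTED_14: tuple[str, ...] = (
    "r_ave", "b_ave", "b_std", "h_ave", "s_ave", "i_ave", "h_std",
    "l_ave", "a_ave", "bstar_ave", "l_std",
    "smoothness", "uniformity", "entropy",
)


@dataclass(frozen=True)
class GrayHistogram:
    """Normalised gray-level histogram of a region.

    ``p`` sums to one over ``levels`` gray levels z_i = 0..levels-1;
    ``sigma2`` is the gray-level variance normalised by (levels-1)^2 so it
    lives on [0, 1].
    """

    p: np.ndarray
    levels: int = 256

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=np.float64)
        if p.size != self.levels or np.any(p < 0):
            raise ValueError("p must be a nonnegative vector of length `levels`")
        if not np.isclose(p.sum(), 1.0):
            raise ValueError("histogram probabilities must sum to 1")
        object.__setattr__(self, "p", p)

    @property
    def sigma2(self) -> float:
        z = np.arange(self.levels, dtype=np.float64)
        mu = float(self.p @ z)
        var = float(self.p @ (z - mu) ** 2)
        return var / (self.levels - 1) ** 2

    @classmethod
    def from_values(cls, values: np.ndarray, levels: int = 256) -> "GrayHistogram":
        """Quantise intensity values on [0, levels-1] to integer bins."""
        z = np.clip(np.rint(np.asarray(values, dtype=np.float64)), 0, levels - 1)
        counts = np.bincount(z.astype(np.int64), minlength=levels)
        if counts.sum() == 0:
            raise ValueError("empty region")
        return cls(p=counts / counts.sum(), levels=levels)


def roi_channel_stats(channel: np.ndarray, mask: np.ndarray) -> tuple[float, float]:
    """Mean and population standard deviation of a channel over the ROI."""
    channel = np.asarray(channel, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if channel.shape != mask.shape:
        raise ValueError("channel/mask geometry mismatch")
    if not mask.any():
        raise ValueError("empty mask")
    vals = channel[mask]
    return float(vals.mean()), float(vals.std())


def texture_smoothness(hist: GrayHistogram) -> float:
    """R = 1 − 1/(1 + σ²) with σ² the normalised gray-level variance.

    Zero for a constant region, approaching 1 for large intensity spread.
    """
    return 1.0 - 1.0 / (1.0 + hist.sigma2)


def texture_uniformity(hist: GrayHistogram) -> float:
    """U = Σ p(z_i)²; maximal (1) when a single level holds all mass."""
    return float(np.sum(hist.p ** 2))


def texture_entropy(hist: GrayHistogram, base: float = 2.0) -> float:
    """e = −Σ p(z_i) log p(z_i), in bits by default; 0·log 0 ≡ 0."""
    p = hist.p[hist.p > 0]
    return float(-np.sum(p * np.log(p)) / np.log(base))


def extract_features(image: np.ndarray, mask: np.ndarray) -> pd.Series:
    """Extract the 21-element feature vector of an image over its ROI.

    Color statistics use the native [0,255] channel scale for RGB and HSI
    (hue in degrees) and the L*a*b* values from the XYZ path; the texture
    measures are computed on the 256-level histogram of the HSI intensity
    restricted to the ROI.
    """
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError("expected an RGB image of shape (H, W, 3)")
    if image.shape[:2] != mask.shape:
        raise ValueError("image/mask geometry mismatch")
    if not mask.any():
        raise ValueError("empty mask")

    pixels = image[mask]                       # (n, 3) ROI pixels
    hsi = to_hsi(pixels)
    lab = to_lab(pixels)

    values: list[float] = []
    for arr in (pixels, hsi, lab):
        for c in range(3):
            values.append(float(arr[:, c].mean()))
            values.append(float(arr[:, c].std()))

    hist = GrayHistogram.from_values(hsi[:, 2])
    values.extend([texture_smoothness(hist), texture_uniformity(hist),
                   texture_entropy(hist)])
    return pd.Series(values, index=list(FEATURE_NAMES), dtype=np.float64)
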