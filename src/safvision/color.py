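"""Per-pixel color-space transforms used for feature extraction.

All transforms take RGB arrays of shape ``(..., 3)`` with channels on the
native 8-bit scale [0, 255] (floats accepted) and are fully vectorised.

The HSI transform follows the classic arccos formulation: hue is measured in
degrees from pure red, saturation is the normalised distance from the gray
axis, and intensity is the plain channel mean.  The L*a*b* path goes through
the CIE XYZ linear combination with channels rescaled to [0, 1] and uses the
piecewise cube-root companding function with breakpoint ``k = 0.008856``; no
white-point division is applied.
"""

from __future__ import annotations

import numpy as np

#: breakpoint of the piecewise cube-root function in the L*a*b* transform
K_LAB = 0.008856

_EPS = 1e-12


def _split(rgb: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    rgb = np.asarray(rgb, dtype=np.float64)
    if rgb.shape[-1] != 3:
        raise ValueError(f"expected trailing axis of size 3, got shape {rgb.shape}")
    return rgb[..., 0], rgb[..., 1], rgb[..., 2]


def to_hsi(rgb: np.ndarray) -> np.ndarray:
    """Convert RGB ([0,255]) to HSI.

    Returns an array of shape ``(..., 3)`` holding (H, S, I) with H in degrees
    [0, 360), S in [0, 1] and I on the input channel scale.  Achromatic pixels
    (R=G=B, hue undefined) get S=0 and, by convention, H=0.
    """
    r, g, b = _split(rgb)
    total = r + g + b
    i = total / 3.0

    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(total > 0, 1.0 - 3.0 * np.minimum(np.minimum(r, g), b)
                     / np.where(total > 0, total, 1.0), 0.0)

    num = 0.5 * ((r - g) + (r - b))
    den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
    chromatic = den > _EPS
    cosarg = np.clip(np.where(chromatic, num / np.where(chromatic, den, 1.0), 1.0),
                     -1.0, 1.0)
    h = np.degrees(np.arccos(cosarg))
    h = np.where(b > g, 360.0 - h, h)
    h = np.where(chromatic & (s > _EPS), h, 0.0)
    h = np.where(h >= 360.0, 0.0, h)
    return np.stack([h, np.clip(s, 0.0, 1.0), i], axis=-1)


def rgb_to_xyz(rgb: np.ndarray) -> np.ndarray:
    """Linear RGB([0,255]) -> XYZ on channels rescaled to [0,1]."""
    r, g, b = _split(rgb)
    r, g, b = r / 255.0, g / 255.0, b / 255.0
    x = 0.607 * r + 0.174 * g + 0.200 * b
    y = 0.299 * r + 0.587 * g + 0.114 * b
    z = 0.066 * g + 1.116 * b
    return np.stack([x, y, z], axis=-1)


def _f(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=np.float64)
    return np.where(t > K_LAB, np.cbrt(t), 7.787 * t + 0.1379)


def to_lab(rgb: np.ndarray) -> np.ndarray:
    """Convert RGB ([0,255]) to L*a*b* via XYZ.

    L* uses ``116·Y^(1/3)`` above the breakpoint and ``903.3·Y`` below it;
    a* = 500·(f(X) − f(Y)), b* = 200·(f(Y) − f(Z)).
    """
    xyz = rgb_to_xyz(rgb)
    x, y, z = xyz[..., 0], xyz[..., 1], xyz[..., 2]
    lstar = np.where(y > K_LAB, 116.0 * np.cbrt(y), 903.3 * y)
    astar = 500.0 * (_f(x) - _f(y))
    bstar = 200.0 * (_f(y) - _f(z))
    return np.stack([lstar, astar, bstar], axis=-1)


def to_chromaticity(rgb: np.ndarray) -> np.ndarray:
    """Normalised chromaticity coordinates r,g,b = channel / (R+G+B).

    Provided for completeness; the default feature set uses raw channel
    statistics, not chromaticity fractions.
    """
    r, g, b = _split(rgb)
    total = r + g + b
    safe = np.where(total > 0, total, 1.0)
    out = np.stack([r / safe, g / safe, b / safe], axis=-1)
    return np.where(total[..., None] > 0, out, 1.0 / 3.0)


def hsi_to_rgb(hsi: np.ndarray) -> np.ndarray:
    """Inverse HSI transform (sector formulation), returning RGB on [0,255].

    Used by the synthetic renderer to realise sampled (H,S,I) colors; values
    are clipped to the 8-bit range after conversion.
    """
    hsi = np.asarray(hsi, dtype=np.float64)
    h, s, i = hsi[..., 0] % 360.0, np.clip(hsi[..., 1], 0, 1), hsi[..., 2]

    r = np.empty_like(h)
    g = np.empty_like(h)
    b = np.empty_like(h)

    def _sector(hh):
        hr = np.radians(hh)
        c1 = i * (1.0 + s * np.cos(hr) / np.cos(np.radians(60.0) - hr))
        c2 = i * (1.0 - s)
        return c1, c2

    sec0 = h < 120.0
    sec1 = (h >= 120.0) & (h < 240.0)
    sec2 = h >= 240.0

    c1, c2 = _sector(np.where(sec0, h, 0.0))
    r[sec0], b[sec0] = c1[sec0], c2[sec0]
    g[sec0] = 3.0 * i[sec0] - (r[sec0] + b[sec0])

    c1, c2 = _sector(np.where(sec1, h - 120.0, 0.0))
    g[sec1], r[sec1] = c1[sec1], c2[sec1]
    b[sec1] = 3.0 * i[sec1] - (r[sec1] + g[sec1])

    c1, c2 = _sector(np.where(sec2, h - 240.0, 0.0))
    b[sec2], g[sec2] = c1[sec2], c2[sec2]
    r[sec2] = 3.0 * i[sec2] - (g[sec2] + b[sec2])

    return np.clip(np.stack([r, g, b], axis=-1), 0.0, 255.0)
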