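"""ISO-3632 chemical strength indices for saffron quality grading.

The three quality markers — crocin (coloring, absorbance at 440 nm),
picrocrocin (flavor, 330 nm) and safranal (aroma, 257 nm) — are expressed on
the A 1% 1cm scale: the absorbance a 1% w/v solution would show in a 1 cm
cuvette, corrected for specimen humidity,

    A_1cm^1%(λ) = A(λ) · 10000 / (0.5 · (100 − H))

where H is the humidity percentage of the 500 mg specimen.  Genuine saffron
satisfies crocin > 120, picrocrocin > 40 and safranal between 20 and 50.
"""

from __future__ import annotations

from dataclasses import dataclass

#: genuineness thresholds on the A 1% 1cm scale
CROCIN_MIN = 120.0
PICROCROCIN_MIN = 40.0
SAFRANAL_RANGE = (20.0, 50.0)


@dataclass(frozen=True)
class Assay:
    """Raw spectrophotometric absorbances plus specimen humidity (percent)."""

    a440: float
    a330: float
    a257: float
    humidity: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.humidity < 100.0:
            raise ValueError("humidity must be in [0, 100)")
        for name in ("a440", "a330", "a257"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class StrengthProfile:
    """A 1% 1cm strengths with per-marker genuineness flags."""

    crocin: float
    picrocrocin: float
    safranal: float
    crocin_genuine: bool
    picrocrocin_genuine: bool
    safranal_genuine: bool

    @property
    def genuine_flags(self) -> tuple[bool, bool, bool]:
        return (self.crocin_genuine, self.picrocrocin_genuine,
                self.safranal_genuine)


def iso_strength(absorbance: float, humidity: float) -> float:
    """A 1% 1cm strength of one marker; strictly increasing in A and in H."""
    if not 0.0 <= humidity < 100.0:
        raise ValueError("humidity must be in [0, 100)")
    if absorbance < 0:
        raise ValueError("absorbance must be nonnegative")
    return absorbance * 10000.0 / (0.5 * (100.0 - humidity))


def absorbance_for_strength(strength: float, humidity: float) -> float:
    """Inverse of :func:`iso_strength`; used by the synthetic assay generator."""
    if not 0.0 <= humidity < 100.0:
        raise ValueError("humidity must be in [0, 100)")
    return strength * 0.5 * (100.0 - humidity) / 10000.0


def grade(crocin: float, picrocrocin: float, safranal: float) -> StrengthProfile:
    """Apply the genuineness thresholds (strict '>' for crocin/picrocrocin,
    inclusive range for safranal)."""
    lo, hi = SAFRANAL_RANGE
    return StrengthProfile(
        crocin=crocin, picrocrocin=picrocrocin, safranal=safranal,
        crocin_genuine=crocin > CROCIN_MIN,
        picrocrocin_genuine=picrocrocin > PICROCROCIN_MIN,
        safranal_genuine=lo <= safranal <= hi,
    )


def strength_profile(assay: Assay) -> StrengthProfile:
    """Convert a raw assay to graded strengths (crocin at 440 nm,
    picrocrocin at 330 nm, safranal at 257 nm)."""
    return grade(
        crocin=iso_strength(assay.a440, assay.humidity),
        picrocrocin=iso_strength(assay.a330, assay.humidity),
        safranal=iso_strength(assay.a257, assay.humidity),
    )
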