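"""Seeded synthetic corpus emulating a seven-class spice-authentication study.

Four adulterant classes (F1 dyed citrus blossom, F2 safflower, F3 mixed
stamen and dyed straw, F4 dyed fibers) and three genuine saffron classes
dried by different methods (G1 microwave, G2 freeze, G3 hot-air).  Each
specimen is rendered as thin curved threads on a bright near-uniform dish:
thread geometry is a random-walk polyline swept with a circular brush, and
per-pixel thread color is drawn from a class-conditional HSI distribution.
Alongside the RGB image the generator emits a two-band spectral frame set
(raw = dark + reflectance x (reference - dark), with a smooth illumination
gradient on the reference) and a spectrophotometric absorbance triplet whose
ISO strengths match the configured class means in expectation.

Everything is a pure function of the configuration, including its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.draw import disk

from .chemistry import Assay, absorbance_for_strength
from .color import hsi_to_rgb
from .spectral import Band, BandImage, FrameRole, SpectralFrameSet


class ConfigurationError(ValueError):
    """Raised for generator configurations that cannot be realised."""


class ClassLabel(str, Enum):
    """The seven study classes; F* are fakes, G* genuine saffron."""

    F1 = "F1"  # dyed citrus blossom
    F2 = "F2"  # safflower
    F3 = "F3"  # mixed stamen and dyed straw
    F4 = "F4"  # dyed fibers
    G1 = "G1"  # microwave-dried saffron
    G2 = "G2"  # freeze-dried saffron
    G3 = "G3"  # hot-air-dried saffron

    @property
    def is_genuine(self) -> bool:
        return self.value.startswith("G")

    @property
    def description(self) -> str:
        return _DESCRIPTIONS[self]


_DESCRIPTIONS = {
    ClassLabel.F1: "dyed citrus blossom",
    ClassLabel.F2: "safflower",
    ClassLabel.F3: "mixed stamen and dyed straw",
    ClassLabel.F4: "dyed fibers",
    ClassLabel.G1: "microwave-dried saffron",
    ClassLabel.G2: "freeze-dried saffron",
    ClassLabel.G3: "hot-air-dried saffron",
}


@dataclass(frozen=True)
class ClassAppearance:
    """Class-conditional appearance, reflectance and chemistry parameters.

    Hue is in degrees, saturation/intensity are fractions of full scale,
    thread geometry is in pixels, band reflectances are fractions in (0, 1)
    and the chemistry means are on the A 1% 1cm strength scale.
    """

    hue_mean: float
    hue_sd: float
    sat_mean: float
    sat_sd: float
    intensity_mean: float
    intensity_sd: float
    thread_count_range: tuple[int, int] = (12, 20)
    thread_length_range: tuple[int, int] = (30, 80)
    thread_width_range: tuple[int, int] = (2, 4)
    red_reflectance_mean: float = 0.5
    nir_reflectance_mean: float = 0.5
    reflectance_sd: float = 0.02
    crocin_mu: float = 100.0
    picrocrocin_mu: float = 30.0
    safranal_mu: float = 15.0
    assay_sd: float = 8.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.hue_mean < 360.0:
            raise ConfigurationError("hue_mean must be in [0, 360)")
        for name in ("hue_sd", "sat_sd", "intensity_sd", "reflectance_sd",
                     "assay_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("sat_mean", "intensity_mean"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        for name in ("red_reflectance_mean", "nir_reflectance_mean"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ConfigurationError(f"{name} must be in (0, 1)")
        for name in ("thread_count_range", "thread_length_range",
                     "thread_width_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ConfigurationError(f"{name} must satisfy 0 <= low <= high")


#: Default class palette.  Red-orange hues for the stigma-like classes, a
#: yellow hue for safflower, a desaturated pale tone for dyed fibers; the
#: chemistry means put fakes far below the genuineness thresholds and order
#: the genuine classes by drying method (hot-air highest crocin/picrocrocin,
#: freeze-dried highest safranal).
DEFAULT_APPEARANCES: dict[ClassLabel, ClassAppearance] = {
    ClassLabel.F1: ClassAppearance(
        hue_mean=22.0, hue_sd=3.0, sat_mean=0.72, sat_sd=0.05,
        intensity_mean=0.46, intensity_sd=0.05,
        red_reflectance_mean=0.55, nir_reflectance_mean=0.45,
        crocin_mu=30.0, picrocrocin_mu=10.0, safranal_mu=5.0),
    ClassLabel.F2: ClassAppearance(
        hue_mean=52.0, hue_sd=3.0, sat_mean=0.80, sat_sd=0.05,
        intensity_mean=0.55, intensity_sd=0.05,
        red_reflectance_mean=0.70, nir_reflectance_mean=0.60,
        crocin_mu=20.0, picrocrocin_mu=8.0, safranal_mu=4.0),
    ClassLabel.F3: ClassAppearance(
        hue_mean=30.0, hue_sd=6.0, sat_mean=0.55, sat_sd=0.09,
        intensity_mean=0.40, intensity_sd=0.08,
        red_reflectance_mean=0.45, nir_reflectance_mean=0.50,
        crocin_mu=110.0, picrocrocin_mu=35.0, safranal_mu=18.0),
    ClassLabel.F4: ClassAppearance(
        hue_mean=38.0, hue_sd=4.0, sat_mean=0.15, sat_sd=0.04,
        intensity_mean=0.65, intensity_sd=0.05,
        red_reflectance_mean=0.75, nir_reflectance_mean=0.75,
        crocin_mu=10.0, picrocrocin_mu=5.0, safranal_mu=2.0),
    ClassLabel.G1: ClassAppearance(
        hue_mean=10.0, hue_sd=3.0, sat_mean=0.85, sat_sd=0.04,
        intensity_mean=0.35, intensity_sd=0.05,
        red_reflectance_mean=0.50, nir_reflectance_mean=0.35,
        crocin_mu=150.0, picrocrocin_mu=50.0, safranal_mu=30.0),
    ClassLabel.G2: ClassAppearance(
        hue_mean=4.0, hue_sd=2.5, sat_mean=0.90, sat_sd=0.03,
        intensity_mean=0.30, intensity_sd=0.04,
        red_reflectance_mean=0.55, nir_reflectance_mean=0.30,
        crocin_mu=190.0, picrocrocin_mu=65.0, safranal_mu=45.0),
    ClassLabel.G3: ClassAppearance(
        hue_mean=16.0, hue_sd=3.0, sat_mean=0.80, sat_sd=0.05,
        intensity_mean=0.25, intensity_sd=0.04,
        red_reflectance_mean=0.40, nir_reflectance_mean=0.25,
        crocin_mu=230.0, picrocrocin_mu=75.0, safranal_mu=25.0),
}


@dataclass(frozen=True)
class CorpusConfig:
    """Complete, seedable description of a synthetic corpus."""

    classes: tuple[tuple[ClassLabel, ClassAppearance], ...] = field(
        default_factory=lambda: tuple(DEFAULT_APPEARANCES.items()))
    images_per_class: int = 60
    image_size: tuple[int, int] = (128, 128)
    background_level: int = 235
    noise_sd: float = 3.0
    humidity_pct: float = 10.0
    spectral_size: tuple[int, int] = (64, 64)
    spectral_noise_sd: float = 50.0
    include_spectral: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.images_per_class < 1:
            raise ConfigurationError("images_per_class must be >= 1")
        if not 0 <= self.background_level <= 255:
            raise ConfigurationError("background_level must be an 8-bit level")
        if not 0.0 <= self.humidity_pct < 100.0:
            raise ConfigurationError("humidity_pct must be in [0, 100)")


# ---------------------------------------------------------------------------
# thread geometry

def _random_walk(rng: np.random.Generator, shape: tuple[int, int],
                 length: float, margin: float) -> np.ndarray:
    """Random-walk polyline vertices (float (n,2) rows of (row, col))."""
    h, w = shape
    pos = np.array([rng.uniform(margin, h - margin),
                    rng.uniform(margin, w - margin)])
    heading = rng.uniform(0.0, 2.0 * np.pi)
    step = 2.0
    pts = [pos.copy()]
    travelled = 0.0
    while travelled < length:
        heading += rng.normal(0.0, 0.35)
        delta = step * np.array([np.sin(heading), np.cos(heading)])
        pos = pos + delta
        # reflect off the canvas borders, keeping the brush inside
        for axis, limit in ((0, h), (1, w)):
            if pos[axis] < margin:
                pos[axis] = 2 * margin - pos[axis]
                heading = -heading if axis == 0 else np.pi - heading
            elif pos[axis] > limit - margin:
                pos[axis] = 2 * (limit - margin) - pos[axis]
                heading = -heading if axis == 0 else np.pi - heading
        pts.append(pos.copy())
        travelled += step
    return np.array(pts)


def _draw_threads(shape: tuple[int, int], appearance: ClassAppearance,
                  rng: np.random.Generator) -> np.ndarray:
    """Boolean raster of all threads (disk brush swept along random walks)."""
    h, w = shape
    max_width = appearance.thread_width_range[1]
    margin = max_width / 2.0 + 1.0
    if 2 * margin >= min(h, w):
        raise ConfigurationError(
            f"threads of width up to {max_width} px cannot fit a {h}x{w} canvas")
    mask = np.zeros(shape, dtype=bool)
    count = int(rng.integers(appearance.thread_count_range[0],
                             appearance.thread_count_range[1] + 1))
    for _ in range(count):
        length = rng.uniform(*appearance.thread_length_range)
        width = rng.uniform(*appearance.thread_width_range)
        pts = _random_walk(rng, shape, length, margin)
        radius = max(width / 2.0, 0.5)
        for row, col in pts:
            rr, cc = disk((row, col), radius, shape=shape)
            mask[rr, cc] = True
    return mask


# ---------------------------------------------------------------------------
# renderers

def render_rgb_image(appearance: ClassAppearance,
                     size: tuple[int, int] = (128, 128),
                     background_level: int = 235,
                     noise_sd: float = 3.0,
                     rng_seed: int | np.random.Generator = 0,
                     return_mask: bool = False):
    """Render one 8-bit RGB specimen image.

    Bright near-uniform background, thread strokes colored per-pixel from the
    class HSI distribution, additive Gaussian noise clipped to [0, 255].
    Identical seeds give byte-identical images.  With ``return_mask=True`` the
    ground-truth stroke raster is returned alongside the image.
    """
    h, w = size
    if h < 64 or w < 64:
        raise ConfigurationError("image size must be at least 64x64")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))

    img = np.full((h, w, 3), float(background_level))
    if appearance.thread_count_range[1] > 0:
        mask = _draw_threads((h, w), appearance, rng)
    else:
        mask = np.zeros((h, w), dtype=bool)

    n_fg = int(mask.sum())
    if n_fg:
        hue = rng.normal(appearance.hue_mean, appearance.hue_sd, n_fg) % 360.0
        sat = np.clip(rng.normal(appearance.sat_mean, appearance.sat_sd, n_fg),
                      0.0, 1.0)
        inten = np.clip(rng.normal(appearance.intensity_mean,
                                   appearance.intensity_sd, n_fg),
                        0.0, 1.0) * 255.0
        img[mask] = hsi_to_rgb(np.stack([hue, sat, inten], axis=-1))

    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return (img, mask) if return_mask else img


#: reflectance of the empty dish area in both bands
BACKGROUND_REFLECTANCE = 0.05
#: nominal reference-surface digital number (16-bit scale) and dark level
REFERENCE_LEVEL = 40000.0
DARK_LEVEL = 2000.0


def render_spectral_set(appearance: ClassAppearance,
                        size: tuple[int, int] = (64, 64),
                        noise_sd: float = 50.0,
                        rng_seed: int | np.random.Generator = 0,
                        return_truth: bool = False):
    """Render raw/reference/dark frames for both bands of one specimen.

    Raw = dark + reflectance x (reference - dark) + noise, so flat-field
    calibration recovers the drawn per-pixel reflectance in expectation.  The
    reference frames carry a smooth illumination gradient so that the
    flat-fielding is non-trivial.  ``return_truth`` additionally returns the
    per-band true reflectance maps and the thread raster.
    """
    h, w = size
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))

    mask = _draw_threads((h, w), appearance, rng)
    cols = np.linspace(-1.0, 1.0, w)[None, :]
    rows = np.linspace(-1.0, 1.0, h)[:, None]

    frames: dict[str, BandImage] = {}
    truth: dict[str, np.ndarray] = {"mask": mask}
    for band, refl_mean, tilt in (
            (Band.RED, appearance.red_reflectance_mean, 0.12),
            (Band.NIR, appearance.nir_reflectance_mean, 0.08)):
        reference = REFERENCE_LEVEL * (1.0 + tilt * cols + 0.5 * tilt * rows)
        dark = np.full((h, w), DARK_LEVEL)
        refl = np.full((h, w), BACKGROUND_REFLECTANCE)
        n_fg = int(mask.sum())
        if n_fg:
            refl[mask] = np.clip(
                rng.normal(refl_mean, appearance.reflectance_sd, n_fg),
                1e-4, 1.0)
        raw = dark + refl * (reference - dark)
        if noise_sd > 0:
            raw = raw + rng.normal(0.0, noise_sd, raw.shape)
        raw = np.maximum(raw, 0.0)
        key = "red" if band is Band.RED else "nir"
        frames[f"{key}_raw"] = BandImage(raw, band, FrameRole.SAMPLE)
        frames[f"reference_{key}"] = BandImage(reference, band, FrameRole.REFERENCE)
        frames[f"dark_{key}"] = BandImage(dark, band, FrameRole.DARK)
        truth[f"reflectance_{key}"] = refl

    out = SpectralFrameSet(**frames)
    return (out, truth) if return_truth else out


def generate_assay(appearance: ClassAppearance, humidity_pct: float = 10.0,
                   rng_seed: int | np.random.Generator = 0) -> Assay:
    """Draw one absorbance triplet whose ISO strengths match the class means
    in expectation (negative draws clipped at zero)."""
    if not 0.0 <= humidity_pct < 100.0:
        raise ValueError("humidity_pct must be in [0, 100)")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    strengths = {
        "crocin": appearance.crocin_mu,
        "picrocrocin": appearance.picrocrocin_mu,
        "safranal": appearance.safranal_mu,
    }
    drawn = {k: max(rng.normal(mu, appearance.assay_sd), 0.0) if appearance.assay_sd > 0
             else mu
             for k, mu in strengths.items()}
    return Assay(
        a440=absorbance_for_strength(drawn["crocin"], humidity_pct),
        a330=absorbance_for_strength(drawn["picrocrocin"], humidity_pct),
        a257=absorbance_for_strength(drawn["safranal"], humidity_pct),
        humidity=humidity_pct,
    )


# ---------------------------------------------------------------------------
# corpus assembly

@dataclass
class CorpusItem:
    """One generated specimen: image, optional spectral set, assay, truth."""

    item_id: str
    label: ClassLabel
    seed: int
    image: np.ndarray
    truth_mask: np.ndarray
    assay: Assay
    spectral: SpectralFrameSet | None = None


@dataclass
class Corpus:
    """In-memory corpus plus its manifest; optionally mirrored on disk."""

    config: CorpusConfig
    items: list[CorpusItem]
    manifest: pd.DataFrame


def generate_corpus(config: CorpusConfig,
                    out_dir: str | Path | None = None) -> Corpus:
    """Generate the full corpus (images + spectral sets + assays + manifest).

    Per-item seeds are derived deterministically from the corpus seed and
    recorded in the manifest, so any single item can be re-rendered in
    isolation.  When ``out_dir`` is given, images are written as 8-bit RGB
    PNGs, spectral frames as 16-bit single-band PNGs, and the manifest and
    configuration as CSV/YAML.
    """
    labels = [lbl for lbl, _ in config.classes]
    if len(set(labels)) != len(labels):
        raise ConfigurationError("duplicate class labels in configuration")

    n_items = len(config.classes) * config.images_per_class
    master = np.random.default_rng(config.seed)
    item_seeds = master.integers(0, 2**31 - 1, size=n_items)

    items: list[CorpusItem] = []
    rows: list[dict] = []
    idx = 0
    for label, appearance in config.classes:
        for j in range(config.images_per_class):
            seed = int(item_seeds[idx])
            image, truth = render_rgb_image(
                appearance, config.image_size, config.background_level,
                config.noise_sd, np.random.default_rng([seed, 0]),
                return_mask=True)
            spectral = None
            if config.include_spectral:
                spectral = render_spectral_set(
                    appearance, config.spectral_size, config.spectral_noise_sd,
                    np.random.default_rng([seed, 1]))
            assay = generate_assay(appearance, config.humidity_pct,
                                   np.random.default_rng([seed, 2]))
            item_id = f"{label.value}_{j:03d}"
            items.append(CorpusItem(item_id, label, seed, image, truth,
                                    assay, spectral))
            rows.append({
                "id": item_id,
                "path": f"images/{item_id}.png",
                "band_paths": (f"spectral/{item_id}_red.png;"
                               f"spectral/{item_id}_nir.png"
                               if config.include_spectral else ""),
                "class": label.value,
                "seed": seed,
            })
            idx += 1

    manifest = pd.DataFrame(rows)
    corpus = Corpus(config=config, items=items, manifest=manifest)
    if out_dir is not None:
        write_corpus(corpus, out_dir)
    return corpus


def write_corpus(corpus: Corpus, out_dir: str | Path) -> Path:
    """Persist a corpus: PNG images, 16-bit band frames, manifest, config."""
    import imageio.v3 as iio
    import yaml

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    if corpus.config.include_spectral:
        (out / "spectral").mkdir(exist_ok=True)
    for item in corpus.items:
        iio.imwrite(out / "images" / f"{item.item_id}.png", item.image)
        if item.spectral is not None:
            for key, frame in (("red", item.spectral.red_raw),
                               ("nir", item.spectral.nir_raw)):
                px = np.clip(np.rint(frame.pixels), 0, 65535).astype(np.uint16)
                iio.imwrite(out / "spectral" / f"{item.item_id}_{key}.png", px)
    corpus.manifest.to_csv(out / "manifest.csv", index=False)

    cfg = asdict(corpus.config)
    cfg["classes"] = [{"label": lbl.value, **asdict(app)}
                      for lbl, app in corpus.config.classes]
    (out / "corpus_config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))

    assays = pd.DataFrame([
        {"id": item.item_id, "class": item.label.value,
         "A440": item.assay.a440, "A330": item.assay.a330,
         "A257": item.assay.a257, "H": item.assay.humidity}
        for item in corpus.items])
    assays.to_csv(out / "assays.csv", index=False)
    return out
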