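"""Synthetic generator: determinism, class structure, physical consistency."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import safvision as sv
from safvision.chemistry import strength_profile
from safvision.classifiers import KNNClassifier, accuracy
from safvision.features import FEATURE_NAMES
from safvision.pipeline import extract_feature_table, feature_matrix
from safvision.synth import ConfigurationError


def test_render_is_deterministic():
    app = sv.DEFAULT_APPEARANCES[sv.ClassLabel.G3]
    a = sv.render_rgb_image(app, rng_seed=42)
    b = sv.render_rgb_image(app, rng_seed=42)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, sv.render_rgb_image(app, rng_seed=43))


def test_no_threads_no_noise_gives_constant_background():
    app = dataclasses.replace(sv.DEFAULT_APPEARANCES[sv.ClassLabel.F1],
                              thread_count_range=(0, 0))
    image = sv.render_rgb_image(app, background_level=235, noise_sd=0.0,
                                rng_seed=0)
    assert (image == 235).all()


def test_red_hue_foreground_pixels_are_red_dominant():
    app = dataclasses.replace(sv.DEFAULT_APPEARANCES[sv.ClassLabel.G1],
                              hue_mean=0.0, sat_mean=0.9)
    image, mask = sv.render_rgb_image(app, noise_sd=0.0, rng_seed=1,
                                      return_mask=True)
    # independent pixel scan over the rendered foreground
    fg = image[mask].astype(int)
    assert np.mean(fg[:, 0] > fg[:, 2]) >= 0.99


def test_threads_that_cannot_fit_are_rejected():
    app = dataclasses.replace(sv.DEFAULT_APPEARANCES[sv.ClassLabel.G1],
                              thread_width_range=(100, 100))
    with pytest.raises(ConfigurationError, match="cannot fit"):
        sv.render_rgb_image(app, size=(64, 64), rng_seed=0)


def test_minimum_canvas_enforced():
    with pytest.raises(ConfigurationError, match="64x64"):
        sv.render_rgb_image(sv.DEFAULT_APPEARANCES[sv.ClassLabel.G1],
                            size=(32, 32), rng_seed=0)


# --- spectral sets ---------------------------------------------------------


def test_spectral_calibration_recovers_half_reflectance_exactly():
    app = dataclasses.replace(sv.DEFAULT_APPEARANCES[sv.ClassLabel.F3],
                              red_reflectance_mean=0.5, reflectance_sd=0.0)
    frames, truth = sv.render_spectral_set(app, noise_sd=0.0, rng_seed=9,
                                           return_truth=True)
    refl = sv.calibrate(frames.red_raw, frames.reference_red, frames.dark_red)
    np.testing.assert_allclose(refl.pixels[truth["mask"]], 0.5, atol=1e-12)


def test_spectral_per_pixel_truth_recovery_with_sd():
    app = sv.DEFAULT_APPEARANCES[sv.ClassLabel.F3]  # reflectance_sd > 0
    frames, truth = sv.render_spectral_set(app, noise_sd=0.0, rng_seed=9,
                                           return_truth=True)
    refl = sv.calibrate(frames.nir_raw, frames.reference_nir, frames.dark_nir)
    np.testing.assert_allclose(refl.pixels[truth["mask"]],
                               truth["reflectance_nir"][truth["mask"]],
                               atol=1e-10)


# --- assays ----------------------------------------------------------------


def test_assay_inverts_iso_arithmetic():
    app = dataclasses.replace(sv.DEFAULT_APPEARANCES[sv.ClassLabel.G1],
                              crocin_mu=200.0, assay_sd=0.0)
    assay = sv.generate_assay(app, humidity_pct=10.0, rng_seed=0)
    assert assay.a440 == pytest.approx(200 * 0.5 * 90 / 10000)  # = 0.9


def test_assay_zero_mean_gives_zero_absorbance():
    app = dataclasses.replace(sv.DEFAULT_APPEARANCES[sv.ClassLabel.F4],
                              crocin_mu=0.0, assay_sd=0.0)
    assert sv.generate_assay(app, rng_seed=0).a440 == 0.0


def test_assay_seed_determinism():
    app = sv.DEFAULT_APPEARANCES[sv.ClassLabel.G2]
    a = sv.generate_assay(app, rng_seed=5)
    b = sv.generate_assay(app, rng_seed=5)
    assert (a.a440, a.a330, a.a257) == (b.a440, b.a330, b.a257)


def test_assay_humidity_validation():
    with pytest.raises(ValueError):
        sv.generate_assay(sv.DEFAULT_APPEARANCES[sv.ClassLabel.G1],
                          humidity_pct=100.0)


def test_mean_crocin_ordering_safflower_microwave_hotair():
    """Generated class means reproduce the expected ordering F2 < G1 < G3."""
    means = {}
    for label in (sv.ClassLabel.F2, sv.ClassLabel.G1, sv.ClassLabel.G3):
        app = sv.DEFAULT_APPEARANCES[label]
        crocins = [strength_profile(sv.generate_assay(app, 10.0, s)).crocin
                   for s in range(40)]
        means[label] = np.mean(crocins)
    assert means[sv.ClassLabel.F2] < means[sv.ClassLabel.G1] \
        < means[sv.ClassLabel.G3]


# --- corpus ----------------------------------------------------------------


def test_small_corpus_counts_and_manifest(small_corpus):
    assert len(small_corpus.items) == 7 * 6
    assert len(small_corpus.manifest) == 42
    counts = small_corpus.manifest["class"].value_counts()
    assert (counts == 6).all() and len(counts) == 7
    assert set(small_corpus.manifest.columns) == \
        {"id", "path", "band_paths", "class", "seed"}


def test_single_image_per_class_manifest():
    cfg = sv.CorpusConfig(images_per_class=1, include_spectral=False, seed=2)
    corpus = sv.generate_corpus(cfg)
    assert len(corpus.manifest) == 7


def test_corpus_reruns_are_identical():
    cfg = sv.CorpusConfig(images_per_class=2, include_spectral=False, seed=8)
    a = sv.generate_corpus(cfg)
    b = sv.generate_corpus(cfg)
    assert a.manifest.equals(b.manifest)
    for x, y in zip(a.items, b.items):
        assert np.array_equal(x.image, y.image)
        assert x.assay == y.assay


def test_corpus_rejects_invalid_config():
    with pytest.raises(ConfigurationError):
        sv.CorpusConfig(images_per_class=0)
    dup = ((sv.ClassLabel.F1, sv.DEFAULT_APPEARANCES[sv.ClassLabel.F1]),) * 2
    with pytest.raises(ConfigurationError, match="duplicate"):
        sv.generate_corpus(sv.CorpusConfig(classes=dup, images_per_class=1))


def test_hue_separation_dial_never_hurts_knn():
    """Widening the hue gap between two classes never lowers KNN accuracy."""
    accs = []
    for gap in (0.0, 15.0, 40.0):
        base = sv.DEFAULT_APPEARANCES[sv.ClassLabel.G1]
        a = dataclasses.replace(base, hue_mean=20.0)
        b = dataclasses.replace(base, hue_mean=(20.0 + gap) % 360)
        cfg = sv.CorpusConfig(
            classes=((sv.ClassLabel.F1, a), (sv.ClassLabel.F2, b)),
            images_per_class=12, include_spectral=False, seed=5)
        table = extract_feature_table(sv.generate_corpus(cfg))
        X, y = feature_matrix(table, FEATURE_NAMES)
        tr, te = sv.split(y, sv.SplitSpec(train_fraction=0.5, seed=3))
        model = KNNClassifier(k=3, random_state=0).fit(X[tr], y[tr])
        accs.append(accuracy(y[te], model.predict(X[te])))
    assert accs[0] <= accs[1] <= accs[2]


def test_write_corpus_roundtrip(tmp_path):
    import imageio.v3 as iio

    cfg = sv.CorpusConfig(images_per_class=1, seed=4)
    corpus = sv.generate_corpus(cfg, out_dir=tmp_path)
    assert (tmp_path / "manifest.csv").exists()
    assert (tmp_path / "assays.csv").exists()
    first = corpus.manifest.iloc[0]
    image = iio.imread(tmp_path / first["path"])
    assert np.array_equal(image, corpus.items[0].image)
    red_path = first["band_paths"].split(";")[0]
    assert (tmp_path / red_path).exists()
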