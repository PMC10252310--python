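# Methods

This note documents the models and procedures `safvision` implements, the
defaults it chooses where the underlying approach leaves the design open,
and what the synthetic corpus can and cannot demonstrate.

## The synthetic corpus

The generator emulates a seven-class spice-authentication study: four
adulterant classes (F1 dyed citrus blossom, F2 safflower, F3 mixed stamen
and dyed straw, F4 dyed fibers) and three genuine saffron classes dried by
microwave (G1), freeze-drying (G2) and hot air (G3). The default
configuration produces 60 images per class — 420 images total — at
128×128 pixels, a canvas size chosen so the full corpus renders and
processes in seconds on one CPU.

**Geometry.** Each specimen is a set of thread-like strokes: random-walk
polylines (step 2 px, heading perturbation σ = 0.35 rad, reflective canvas
borders) swept with a circular brush of the configured width. Threads are
hard-edged rather than anti-aliased so the generator can hand the exact
ground-truth stroke raster to the segmentation tests. Per class the thread
count, length and width ranges are configurable; defaults are 12–20 threads
of 30–80 px length and 2–4 px width.

**Color.** Per-pixel thread color is drawn from a class-conditional HSI
distribution (hue in degrees, saturation and intensity as fractions) and
converted to RGB with the sector form of the inverse HSI transform. The
default palette puts the stigma-like classes at red-orange hues (4–30°),
safflower at yellow (52°), and dyed fibers at a desaturated pale tone
(saturation 0.15). Genuine classes are darker (intensity 0.25–0.35) than
fakes, mimicking dense dried stigmas. The background is a near-uniform
bright level (235) and i.i.d. Gaussian pixel noise (σ = 3 digital numbers,
clipped to 8 bits) is added; JPEG artifacts are not simulated and images
are written as PNG so features are bit-stable.

**Spectral frames.** Each specimen also gets a six-frame set per the
two-band rig: raw, reference (100%-reflectance surface) and dark frames at
650 and 850 nm, 64×64 pixels. Raw frames are synthesized as
`dark + ρ·(reference − dark) + noise` with per-pixel thread reflectance ρ
drawn around the class mean (sd 0.02) and a background reflectance of 0.05;
the reference carries a smooth illumination tilt (12% across the red frame,
8% across NIR) so flat-fielding is non-trivial. With noise off,
calibration recovers the drawn reflectance to float precision — a designed
fixed point used by the tests.

**Chemistry.** Assays are drawn on the strength scale (Gaussian around the
class mean, sd 8, clipped at zero) and inverted through the strength
formula to absorbance triplets, so the expected strengths equal the
configured class means. Default class means place the fakes far below the
genuine thresholds, F3 just below (crocin 110), and order the genuine
classes G1 < G2 < G3 in crocin/picrocrocin with G2 highest in safranal.
Specimen humidity defaults to 10%.

**What passing tests do not show.** The corpus has exactly the class
contrasts written into it. Pipeline accuracies near 100% demonstrate
correctness of the machinery (segmentation, transforms, classifier
implementations) under a separable class structure, not the field
difficulty of real adulterant detection: real corpora have shadows, touching
threads, camera noise correlated across pixels, and far subtler color
differences between, say, microwave- and hot-air-dried stigmas.

## Segmentation

Otsu's threshold is computed on the 256-bin green-channel histogram by
exhaustive maximization of the between-class variance over the cut points
`{≤t}` vs `{>t}`; ties break toward the lower level, and an all-one-bin
histogram is reported as degenerate rather than guessed at. The darker
side of the cut is foreground (threads on a bright dish). Cleanup removes
8-connected components smaller than 25 px and then erodes once with a 3×3
cross. Hole-filling is off by default. The area filter is idempotent;
erosion, by construction, is not — coverage guarantees in the tests are
therefore stated against the pre-erosion mask, and the final mask is only
required to stay inside the dilated ground truth.

## Color transforms

HSI uses the arccos hue formula with the standard denominator
`sqrt((R−G)² + (R−B)(G−B))`, which bounds the arccos argument; hue is
reported in degrees [0, 360), with S = 0 and H = 0 by convention for
achromatic pixels. RGB channels stay on [0, 255] for HSI and for all
mean/std features; only the XYZ → L\*a\*b\* path rescales channels to
[0, 1]. L\* uses `116·Y^(1/3)` above the breakpoint k = 0.008856 and
`903.3·Y` below it — note this pair is discontinuous at Y = k (24.0 vs
8.0); the package implements the transformation as specified rather than
the continuous variant with the −16 offset. No white-point division is
applied. Chromaticity coordinates r, g, b are implemented but unused by
the default feature set, whose channel statistics are on the raw scale.

## Texture features

The three first-order measures are computed on the 256-level histogram of
the HSI intensity restricted to the ROI (background pixels are excluded —
including the masked zeros would dominate the histogram). Variance is
normalized by (L−1)² = 255² so smoothness lives on [0, 1); entropy uses
log base 2 (bits) — a monotone rescaling of any other base and
configurable.

## Spectral features

Calibration is pixelwise `(sample − dark)/(reference − dark)`; pixels with
a zero denominator are flagged invalid and excluded, and a frame set where
the reference equals dark on a majority of pixels is a calibration failure.
Calibrated values are not clipped to [0, 1] (clipping would bias ROI
means). Spectral segmentation thresholds the calibrated NIR band and keeps
the brighter side (threads out-reflect the dish in NIR in this rig).
Skewness uses the population (biased) moment estimator, defined as 0 for a
constant region; a std below 10⁻¹² of the mean's magnitude is treated as
exactly constant to avoid amplifying float round-off into a meaningless
third moment.

## Chemistry

Strength is `A·10000/(0.5·(100−H))`, strictly increasing in both the
absorbance and the humidity percentage; H ≥ 100 is rejected. Genuineness
flags use a strict `>` for the crocin (120) and picrocrocin (40) thresholds
and an inclusive 20–50 range for safranal. The wavelength-to-marker
mapping is 440 nm crocin, 330 nm picrocrocin, 257 nm safranal.

## Classifiers

All families share one estimator contract: z-score normalization fitted on
the training partition (distance-based families require it; it is exact
under per-column rescaling, which the tests exploit), deterministic
behaviour given `random_state`, and label handling that is equivariant
under class relabeling.

- **RBF network** — hidden units `h_j(x) = exp(−‖x−c_j‖²/(2σ²))` with one
  shared spread σ; centers from seeded k-means (25 by default, capped at
  the training size); linear output layer solved by ridge regression
  (λ = 10⁻⁶) against one-hot targets; prediction is the arg-max output.
  Naming a first-order training algorithm fine-tunes the output layer from
  the closed-form solution; the second-order least-squares algorithms are
  recorded as metadata because the closed-form solve already minimizes the
  same objective.
- **MLP** — sigmoid hidden layers (default one layer of 12), linear output
  against one-hot targets. T1 is a full Levenberg–Marquardt loop on the
  analytically-computed residual Jacobian (verified against finite
  differences); T2 adds MacKay's Bayesian-regularization updates of the
  weight-decay and noise precisions via the effective-parameter count
  γ = P − α·tr(H⁻¹). T4–T8 (Rprop and the gradient-descent family) are
  first-order loops on the sample-normalized squared error; T3 and
  T10–T12 map to conjugate-gradient, T9 to BFGS and T13 to a memory-1
  L-BFGS. Output-layer weights start at zero so the whole training
  trajectory permutes exactly with the target columns.
- **KNN** — Euclidean distance; vote ties break by the smaller summed
  distance among tied classes, then lexicographic class code.
- **SVM** — one-vs-one RBF-kernel SVC (scikit-learn backend) with fixed
  defaults C = 10, gamma = "scale"; a `tune_svm` helper runs a 5-fold CV
  grid when data-driven defaults are wanted.
- **SOM** — 10×10 grid, Gaussian neighborhood and learning rate decaying
  exponentially (0.5 → 0.01, σ from half the grid to 0.5) over 200 epochs
  of per-sample updates; units are labeled post hoc by majority vote with
  a label-symmetric tie-break (nearest mapped sample), and unvisited units
  inherit the nearest labeled unit's class.
- **LVQ** — LVQ1 with 2 codebooks per class initialized at class-wise
  k-means centers (one shared k-means seed keeps initialization
  equivariant under relabeling), learning rate 0.1 decaying linearly to 0
  over 100 epochs.

Accuracy is reported as `100·n_p/(n_p+n_mp)` per partition; the "total"
figure pools train and test predictions, so it is the sample-weighted
combination of the two.

## Experiments

Splits are stratified: the per-class training count is
`round(fraction · class size)`, clamped so both partitions stay nonempty;
a fraction of 1.0 is rejected. Sweeps are one-factor-at-a-time with the
other factors held at the base estimator's values. The sensitivity
analysis reuses the tabulated feature groups (All, the fixed 14-feature
subset, per-space and per-statistic groups, texture); the reduced set's
duplicated printed name "b_ave" is resolved as blue-channel mean first and
b\* mean second, and the mapping is overridable by passing custom groups.
The 14-feature subset is a named fixed group; the trial-and-error search
that produced it is not re-run.

Fisher LSD: one-way ANOVA MSE with
`LSD = t(1−α/2, df_E)·sqrt(MSE·(1/n_i + 1/n_j))` (the equal-n form
`t·sqrt(2·MSE/n)` falls out as a special case); a pair is significant when
its mean difference reaches the LSD, with the degenerate MSE = 0 /
zero-difference case counted as not significant so identical groups share
a letter. The compact letter display uses the insert-and-absorb procedure;
letters are ordered by descending group mean.

## Numerical choices and degenerate inputs

- Otsu on an effectively constant channel raises an "empty foreground"
  error instead of returning an arbitrary cut.
- The arccos argument in the hue formula is clipped to [−1, 1] before
  evaluation.
- Histograms quantize intensities by rounding to the nearest of 256 levels.
- k-means center counts are capped at the number of training samples; a
  spread σ ≤ 0, k > n, or a single-class training set raise errors.
- All random draws flow from `numpy.random.default_rng` seeded by the
  configuration; per-item corpus seeds are derived from the corpus seed
  and recorded in the manifest so single items can be re-rendered.

## Known limitations

- The renderer does not model shadows, specular highlights, Bayer mosaics,
  JPEG compression, or camera spectral response; segmentation difficulty
  is therefore far below field conditions.
- The spectral corpus assumes per-band dark frames and a rigid
  reference/dark acquisition; drift between frames is not simulated.
- The ISO strength formula is implemented exactly as stated, including its
  compressed treatment of the moisture-corrected dry-mass convention.
- Classifier hyperparameters beyond the RBF design parameters (MLP
  topology, SVM kernel constants, SOM grid, LVQ codebook counts) are
  engineering defaults, all exposed in the constructors.
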