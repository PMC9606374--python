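# Methods

This note records the mathematical definitions, numerical choices and
design decisions behind `woundtherm`, in pipeline order.

## 1. Pre-processing (`woundtherm.preprocess`)

Thermal imagers export pseudo-colour rasters, not temperatures. The
pipeline therefore works on a normalised grey surrogate of temperature:

- **Logo removal.** Handheld imagers stamp a vendor logo into the frame.
  The configured rectangle is replaced by the median colour of a 2-pixel
  ring around it before any analysis.
- **Grey conversion.** Default is Rec. 709 luminance
  `0.2126 R + 0.7152 G + 0.0722 B`. A `colormap_inverse` mode inverts a
  known palette by nearest-neighbour lookup against its 256-entry LUT.
- **Normalisation.** Min–max to [0, 1] per image (a constant image maps
  to zeros with a warning). Absolute temperature is discarded by
  design: only relative spatial structure enters the features.
- **Masking.** Otsu threshold (or a fixed value) on the grey image,
  interior hole filling, binary erosion with a disk structuring element
  (radius 2 by default) to trim boundary mixing pixels, then the largest
  connected component. Pixels outside the mask are *excluded* from the
  GLCM, not zero-filled — zero-filling would fabricate co-occurrences
  between the wound boundary and an artificial black background.

## 2. GLCM texture features (`woundtherm.texture`)

Eligible grey values are quantized to `Ng = 16` equal-width levels
1…Ng over the per-bed [min, max]. The co-occurrence matrix counts
ordered level pairs at offset (angle 90°, distance 1) where **both**
endpoints are mask-eligible; the transpose is accumulated as well
(symmetric GLCM) and the matrix is normalised to probabilities
`p(i, j)`.

All 19 features use level indices `i, j ∈ 1…Ng`, natural logarithms and
the convention `0·log 0 = 0`: energy, contrast, correlation, sum of
squares (variance), sum average, sum variance, entropy, sum entropy,
difference entropy, information measure of correlation, homogeneity
(inverse difference moment), autocorrelation, dissimilarity, cluster
shade, cluster prominence, maximum probability, inverse difference
homogeneity `Σ p/(1+|i−j|)`, and the two normalised variants
`Σ p/(1+|i−j|/Ng)` and `Σ p/(1+(i−j)²/Ng²)`.

Numerical conventions:

- A single-level (constant) bed makes marginal variances zero;
  correlation and the information measure are then reported as 0 and the
  feature vector is flagged `degenerate` rather than raising.
- `Hom ≤ idHom` always: `(i−j)² ≥ |i−j|` for integer levels, so the
  inverse-difference denominator is never larger than the
  inverse-difference-moment one.
- The implementation is vectorised; the test suite checks it against a
  deliberately naive pure-Python double loop to |Δ| < 1e-10 and against
  scikit-image's `graycomatrix`/`graycoprops` where features overlap.

## 3. Feature ranking (`woundtherm.stats`)

Each feature is tested unhealed vs healed with a two-sided Mann–Whitney
U test. For pooled samples of at most 20 observations the p-value is
exact: without ties, via the classical count-distribution recursion of
the U statistic; with ties, by enumeration over group assignments. For
larger samples a tie-corrected normal approximation with continuity
correction is used. Effect sizes: Cohen's d (pooled SD) and the
rank-biserial correlation `2U/(n_x n_y) − 1`. Features are ranked by
p-value; an optional `one_per_subject` filter keeps the first image per
subject to avoid pseudo-replication.

## 4. PCA (`woundtherm.pca`)

PCA is computed by SVD of the centred (by default unstandardised)
training matrix. Component signs are fixed (largest-magnitude loading
positive) so results are bit-reproducible. Three components are kept by
default; `select_n_components` returns the smallest k whose cumulative
explained variance reaches a threshold (default 99.99 %, which the
default synthetic cohorts reach with k ≤ 3). Held-out data is only ever
centred with the *training* mean and projected onto the *training*
components — a mutation test asserts that perturbing test rows cannot
change the fitted model.

## 5. Bayesian-evidence network (`woundtherm.bnn`)

The classifier is a 3–h–1 network (tanh hidden layer, logistic output)
trained by minimising

```
M(w) = G(w) + α E_W,   G = −Σ [t ln y + (1−t) ln(1−y)],   E_W = ½ Σ w²
```

with L-BFGS-B. The weight-decay coefficient is re-estimated by the
evidence update `α ← γ / (2 E_W)` with `γ = Σ λ/(λ+α)` the number of
well-determined parameters, iterated to convergence. The Hessian uses
the Gauss–Newton form `Σ y(1−y) g gᵀ + αI`, which is positive
semi-definite; eigenvalues are floored at 1e-10 before the
log-determinant.

The hidden-layer width h ∈ {1, …, 9} is chosen by maximising the Laplace
log evidence

```
ln Ev(h) = −G − α E_W − ½ ln det A + (W/2) ln α,   W = 5h + 1
```

over several random restarts per width, ties broken toward smaller h.

**Symmetry factor.** Textbook accounts sometimes add `ln h! + h ln 2`
for hidden-unit permutation/sign symmetries. With MAP training under
re-estimated weight decay this term makes the evidence *strictly
increasing* in h: spare hidden units shut off (weights → 0), costing
nothing in fit, Occam factor or the α terms, while the symmetry term
keeps growing. Model selection then always returns the largest width
offered, defeating the purpose of the evidence comparison. The factor
is therefore implemented but **off by default**
(`log_evidence(..., include_symmetry=True)` enables it); with it off the
evidence shows the expected Occam behaviour (interior maximum at small
h on data generated by a small teacher network).

**Occam demonstration conditions.** The acceptance test generates labels
from a width-2 teacher network (weights scaled ×3.0) with logit noise
σ = 2.0 on n = 45 points. These two constants are the package's own
simulation design: the Occam property needs a noise regime in which
extra capacity cannot cheaply fit the labels, and a (σ, scale) scan
showed argmax h ≤ 4 in 16/20 seeds at these values.

## 6. Evaluation (`woundtherm.evaluate`)

Twenty stratified 70/30 holdout repetitions (per-class test size
`floor(n_class·0.3)`, so a 47/17 cohort gives a 45-row training and a
14+5 test set). Per repetition: PCA fit on the training rows, width
selection by evidence, sensitivity (unhealed = positive class) and
specificity on both sides, training ROC by threshold sweep and
trapezoidal AUC (equal to the concordance statistic). Aggregates are
mean and SD (ddof = 1) over successful repetitions; the "best"
repetition maximises test sensitivity, tie-broken by specificity. All
randomness derives from `SeedSequence([master_seed, rep_index])`, so
reports are byte-reproducible.

Some acceptance-scale runs use `restarts=2, h_range=(1…5)` instead of
the library defaults (5 restarts, h ≤ 9) purely to stay inside CI
runtime budgets; the defaults are exercised at single-repetition scale
by `scripts/acceptance.py`.

## 7. Synthetic cohort generator (`woundtherm.synthetic`)

Each frame (160×120) is composed of: a vertical background temperature
gradient; an elliptical wound (random centre, axes, orientation,
rejected deterministically if it would touch the logo block) whose bed
is `base level + amplitude × texture`; Gaussian pixel noise; a bright
logo rectangle; and an "ironbow"-style palette whose channel ramps are
placed at the Rec. 709 weights so that luminance inverts the palette
exactly.

The texture field is a Gaussian random field (Gaussian-filtered white
noise, σ = correlation length, re-standardised) passed through the skew
transform `(z + s(z²−1)/√2)/√(1+s²)`. Class separation is carried by the
**correlation length** (unhealed 1.5 px vs healed 3.0 px) and **skew**
(1.2 vs 0), not by the amplitude: per-image min–max quantization
normalises amplitude away, whereas a shorter correlation length directly
raises GLCM contrast at distance 1. This yields the documented
directions (contrast, cluster shade/prominence higher and normalised
inverse-difference moment lower in unhealed beds).

What the generator does **not** emulate: absolute temperatures and
emissivity, camera optics and fixed-pattern noise, wound-edge
granulation structure, limb curvature, or any longitudinal healing
dynamics. It is a benchmark for the *pipeline*, not a physiological
model: results on it demonstrate correctness and recoverability, not
clinical performance.

## 8. Determinism

Every stochastic step takes an explicit seed and uses
`numpy.random.default_rng`/`SeedSequence` derivation; CSV floats are
written at 12 significant digits and JSON with sorted keys. Rerunning
any CLI command or `scripts/acceptance.py` with the same seed reproduces
every output byte for byte (acceptance criterion and test).
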