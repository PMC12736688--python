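# Methods

This note documents the models, algorithms and design choices behind
`ricesits`, in the order data flows through the pipeline.

## Problem setting

Mapping paddy rice from optical satellite image time series (SITS) in
cloud-prone, fragmented agricultural landscapes. Each sample is a per-pixel
(optionally per-patch) sequence of Sentinel-2-style surface reflectances —
blue (B2), red (B4), near-infrared (B8) and shortwave-infrared (B11) — with
day-of-year (DOY) stamps and scene-classification (SCL-style) quality codes.
The classifier decides rice (label 1) versus non-rice (label 0) from the
phenological trajectory: rice uniquely combines a flooded transplanting
stage (high LSWI), a steep NDVI green-up through tillering and heading, and
a rapid senescence during ripening.

## Synthetic scene generator

The generator is first-class, tested code: it defines the study conditions
under which every downstream stage is validated without external downloads.

* **Rice (and confuser-crop) NDVI** uses a double-logistic curve, the
  standard phenology family: `base + (peak-base) * L((t-m1)/s1) *
  L(-(t-m2)/s2)` with `L` the logistic function. The green-up midpoint `m1`
  sits 35% into the growth stage and the senescence midpoint `m2` halfway
  through ripening; slopes are tied to the stage lengths. Stage durations
  default to the single-season japonica calendar: transplanting 18 d
  (valid range 10–30), growth 90 d (60–110), ripening 42 d (30–60),
  transplanting onset DOY 165. Defaults for levels: NDVI base 0.18, peak
  0.85; LSWI 0.45 flooded decaying to 0.05 dry (logistic decay centred 55%
  into growth). The derivative of this family changes sign exactly once, so
  green-up/senescence sign checks on temporal differences are analytically
  grounded.
* **Non-rice templates**: water (NDVI −0.15, LSWI 0.60), urban (0.12,
  −0.05), forest (0.72 with a ±0.06 seasonal sinusoid, 0.25), and
  `other_crop`, a phase-shifted double-logistic (transplant DOY 130, no
  flooding signal) acting as the spectral confuser whose separation
  requires temporal dynamics.
* **Bands from indices.** Reflectances are constructed so that the index
  formulas invert exactly: `B4 = B8(1−NDVI)/(1+NDVI)`,
  `B11 = B8(1−LSWI)/(1+LSWI)`, B2 fixed at 0.04, and B8 tied to greenness
  (`0.12 + 0.28·max(NDVI,0)`). Recomputing NDVI/LSWI from the emitted bands
  reproduces the target curves to ≤1e−9 when no [0,1] clipping occurs.
* **Polygon structure.** Points are sampled in polygons (fields): each
  polygon draws jittered curve parameters (e.g. transplant DOY ± 4 d,
  levels ± 0.02–0.03) shared by its points, and each point adds independent
  Gaussian index noise (default sd 0.05). This within-polygon correlation
  is what makes polygon-group splitting meaningful.
* **Cloud gaps** are Bernoulli per timestep (default rate 0.3) encoded as a
  high-probability-cloud quality code; at least one clear step per sample
  is guaranteed. Default sampling grid: DOY 152–304 at a 5-day revisit
  (31 steps), matching the rice season acquisition cadence.
* **Scale.** The default configuration is 2,000 polygons × 3 points for
  each of five classes (30,000 points, balanced, 10,000 polygons),
  mirroring the study's sample design; tests and the acceptance script use
  scaled-down scenes where noted.
* Determinism: four independent child streams (polygon jitter, pixel
  noise, gaps, patch texture) derive from one seed, so the same seed gives
  byte-identical datasets and noise-free variants share polygon curves.

What the generator does **not** emulate: spatial autocorrelation of cloud
cover, mixed pixels and field-boundary effects, atmospheric residuals,
inter-annual phenology shifts, label noise, and class imbalance. The
synthetic task is therefore substantially easier than real mapping: the
classifier reaches near-perfect held-out accuracy at the default noise
levels, and the ablation orderings asserted in the acceptance tests often
hold as ties. Passing these tests demonstrates the pipeline's contracts
(no leakage, masking correctness, convergence, metric arithmetic), not the
real-data effect sizes of the architecture.

## Preprocessing

Order of operations: quality masking → Savitzky–Golay smoothing →
harmonic-regression gap filling, applied to the index series (NDVI, LSWI,
EVI), not raw bands.

* Default mask set {3, 6, 8, 9, 10, 11}: cloud shadow, water, medium/high
  cloud, cirrus, snow (configurable; code conventions vary).
* SG smoothing: window 7, order 2, on the valid subsequence treated as
  equally spaced (standard practice for quasi-regular revisit series);
  `mode="interp"` boundaries, so polynomials of degree ≤ 2 are reproduced
  exactly. Fewer valid points than the window ⇒ no-op with a warning.
* Harmonic regression: OLS on {1, cos(2πkt/P), sin(2πkt/P)}, K = 2
  harmonics, period P = 365 d — two harmonics capture one green-up/
  senescence cycle plus asymmetry. Requires ≥ 2K+1 valid points and a
  full-rank design (distinct DOYs); failures name the offending sample.
* **Fill-only policy**: fitted values replace only masked slots; valid
  observations are never altered. The batch path solves the per-sample
  normal equations vectorised over samples and is tested to match the
  per-sample path to 1e−9.

## Phenological feature set

Per valid timestep: NDVI = (B8−B4)/(B8+B4), LSWI = (B8−B11)/(B8+B11), and
the standard three-band EVI = 2.5(B8−B4)/(B8+6·B4−7.5·B2+1) (G = 2.5,
C1 = 6, C2 = 7.5, L = 1). Two derivative families act between *consecutive
valid* steps: TDVI, the plain difference VI(t+Δt) − VI(t) (positive in
green-up, negative in senescence), and NCRVI, the relative change
(VI(t₂)−VI(t₁))/VI(t₁) × 100% (baseline-insensitive). Δt is carried as
metadata only; TDVI is a difference, not a rate.

Presets: `baseline` (3 channels), `+tdvi` and `+ncrvi` (6), `complete`
(9: all three indices with both derivative families), and
`ndvi-only-derivatives` (5) for the reading in which only NDVI carries
derivatives. Conventions: the first valid step's derivative channels are 0
(padding-neutral after standardization); a zero denominator emits 0 with a
flag (NDVI/LSWI/EVI guard 1e−8, NCRVI baseline guard 1e−6); invalid steps
emit all-zero features and are excluded by the model mask.

Standardization is per-channel zero-mean/unit-sd fitted **only** on
training samples (sd floored at 1e−8); the frozen statistics are applied
unchanged to validation and test data and stored in the checkpoint.

## Classifier

A transformer encoder over per-timestep tokens (d_model 64, 4 layers,
8 heads, feed-forward 256, GELU, dropout 0.1, post-norm residual blocks),
with four additions around it:

* **Three-branch feature embedding**: a direct affine projection, a
  two-layer GELU perceptron, and a pairwise-interaction branch (all
  C(C+1)/2 elementwise channel products, affinely projected), each to 32
  dims; concatenated (96), recalibrated by squeeze-style channel attention
  (masked mean over time → bottleneck MLP → sigmoid weights), projected to
  d_model. The `linear` variant (single affine projection) is the original
  embedding for ablations.
* **Optional patch branch**: two 3-D convolutions (3³ kernels, stride 1,
  same padding, 64 filters, GELU) over the P×P×4 volume per timestep,
  flattened and mapped to d_model, summed with the feature embedding. Off
  by default so the model runs on pure index sequences; the spatial/
  temporal role of these convolutions is ambiguous in the source
  description and is implemented here as per-timestep patch embedding.
* **Adaptive positional encoding** = learnable embedding of a coarse
  phenological stage (transplanting < DOY 172 ≤ growth < DOY 259 ≤
  ripening; configurable bins) + a learnable affine map of sinusoidal DOY
  features (8 frequencies + linear term). It is a function of DOY only,
  never of sequence position, so irregular sampling is handled naturally.
  The `fixed` variant is the classic parameter-free sinusoid at
  position = DOY.
* **Phenology attention gate**: a lightweight MLP on [token ⊕ positional
  encoding] producing per-timestep, per-dimension sigmoid gates that
  rescale encoder outputs; disabled ⇒ exact identity. With zeroed weights
  the gates are 0.5 (a testable closed form).

Masked steps contribute to nothing: attention adds −1e30 to their key
scores (exp underflows to exactly 0 in float32), pooling is a masked mean,
and all embeddings are per-timestep — so masking a step is *exactly*
equivalent to deleting it, which the tests assert to 1e−10 in float64.
Classification head: masked global average pooling → 32-unit GELU layer →
softmax over 2 classes. Map products threshold the rice probability at
0.5; metrics use argmax.

The network and its training loop run on an in-package reverse-mode
autodiff engine over numpy arrays with fused kernels (affine, packed-QKV
attention, layer norm with residual routing, softmax cross-entropy, 3-D
convolution). Float32 is the working precision; gradient-check tests run
the engine in float64 against numerical differentiation (rel. error
≤ 1e−5). Weight init is Xavier-uniform with zero biases everywhere, seeded.

## Training

Polygon-group splitting shuffles polygons within label strata and cuts at
the target fraction, so no polygon's points straddle train/test; achieved
fractions are exact when points-per-polygon is constant (e.g. 24,000/6,000
at 30,000 points, 20% test). Optimisation: AdamW (lr 1e−3, weight decay
0.01), cross-entropy, batch 32, global gradient-norm clipping at 1.0,
cosine annealing to 0 over the epoch budget (default 100 epochs;
reduce-on-plateau ×0.5 with patience 5 available). An optional inner
polygon-group split (10% of training polygons) provides a monitoring/
plateau validation set; the standardizer is fitted on the training portion
only. Divergent (NaN) losses abort with epoch/batch diagnostics. Runs are
bit-reproducible given a seed on single-threaded execution.

## Evaluation

Positive class = rice. Accuracy, precision, recall, F1, and Cohen's kappa
with Pe = [(TP+FP)(TP+FN) + (FN+TN)(FP+TN)]/N²; undefined ratios are
reported as null with a flag. The McNemar paired test uses discordant
counts b (A correct, B wrong) and c (A wrong, B correct) with the
continuity-corrected statistic (|b−c|−1)²/(b+c) by default (uncorrected
(b−c)²/(b+c) available), p from the χ²(1) upper tail, p = 1 when b+c = 0.
No multiple-comparison adjustment by default; Bonferroni is provided.
Probability summaries report class-conditional histograms of the rice
probability and their overlap coefficient. Area agreement between a mapped
and a reference area is min/max × 100%.

## Problem sizes used by tests and the acceptance script

The test suite and `scripts/acceptance.py` train on a 7,500-point default
scene (500 polygons × 3 points × 5 classes → 6,000 train / 1,500 test) for
10 epochs — the model converges within 1–2 epochs at the default noise —
and run ablation-ordering comparisons on an 800/200-point confuser scene
for 15 epochs. The split-arithmetic checks generate the full 30,000-point
scene. These sizes are the package's chosen study conditions for CPU
execution; all are configurable.

## Known limitations

* GeoTIFF raster inference is not implemented; `predict` consumes CSV
  feature tables. The minimum-mapping-unit post-filter for map products is
  therefore out of scope here.
* The SG filter treats valid observations as equally spaced; with long
  gaps this is an approximation (the harmonic fit, which uses true DOYs,
  does the heavy lifting for gap filling).
* The autodiff engine implements exactly the ops this model needs; it is
  not a general-purpose framework (no higher-order gradients, CPU only).
* NCRVI is unstable near a zero baseline by construction; the guard emits
  flagged zeros rather than extrapolating.
* The feed-forward width follows the explicit value 256 (4× would be 256
  for d_model 64 anyway; the "2× hidden" description that accompanies it
  elsewhere is inconsistent and not followed).
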