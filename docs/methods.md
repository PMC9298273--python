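# Methods

This note documents the models, numerical choices and known limitations
of phenoscreen, in the order data flows through the package.

## Synthetic microscopy model

The generator (`phenoscreen.synthetic`) emulates a three-marker
high-content screen of neuronal cultures at the level of structure the
downstream analysis is sensitive to, not at photorealistic fidelity.

**Geometry.** Cells are placed by rejection sampling with a minimum
separation of 3.2 nuclear radii. Each nucleus is an ellipse (axis ratio
uniform in [1.0, 1.1], random orientation) whose angular radius r(θ) is
perturbed by Fourier modes k = 1…6 with amplitudes drawn
N(0, irregularity/√6) relative to the mean radius; the mode family is
the lowest-complexity shape model whose outline carries a tunable
phenotype. Somata are circles of fixed radius (default 22 px)
*decoupled* from the nucleus parameters — an early coupled design leaked
nuclear size shifts into the βIII-tubulin channel and corrupted the
channel-ablation logic. Neurite trees are branching random walks
(step 2.5 px, heading noise N(0, 0.15) clipped to ±0.5 rad, branch
probability 0.1 per step, hard cap of 400 steps per tree to keep
branching subcritical), rooted at randomly chosen somata; the expected
number of trees per field (`neurite_density`, default 30) is independent
of the cell count (`cell_density`, default 12 per field) for the same
leakage reason. Fragmentation deletes whole 10-step chunks of a walk
with the given probability, so skeleton length decreases monotonically
in the parameter.

**Intensity.** DAPI renders the nucleus mask (per-cell brightness
uniform in [0.8, 1.2]) with a σ = 0.6 px optical softening; BIII renders
somata plus a Gaussian tube of width `neurite_width_px` over the
skeleton. The RBP channel is rendered piecewise-constant on the nucleus
and cytoplasm masks with amplitudes 1 and 1/`rbp_nc_ratio`, so the
rendered nuclear-to-cytoplasmic mean-intensity ratio equals the
parameter exactly up to noise (verified to <1% on the emitted masks).
Each channel is scaled so its 99.9th percentile sits near 20,000 of the
65,535 16-bit counts — leaving headroom and making autocontrast
non-trivial — with a 3% autofluorescence floor. z-stacks blur the
in-focus render with σ = 1.5·|k − focus| px per plane; the
maximum-intensity projection therefore approximately recovers the
in-focus image. Noise is Poisson shot noise plus Gaussian read noise
(default SD 120 counts).

**Hierarchy.** Condition effects are *additive shifts* on the phenotype
vector declared in a single table (`CONDITION_EFFECTS`): the mutant
genotype shrinks and deforms nuclei and fragments/thins the neurite
network; heat applies the same direction at 3/4 magnitude; oxidative
stress lowers the RBP nuclear-to-cytoplasmic ratio; osmotic stress
swells nuclei and somata (an axis distinct from the mutant's). Shift
magnitudes are free parameters of the simulation — no published estimate
of the real morphological effect sizes exists — and were chosen once so
that a desk-scale CNN can detect each condition; all recovery claims are
therefore about ordering and localization, not effect magnitude.
Recovery time attenuates a shift with a 1-hour half-life. Cell lines and
experiments contribute multiplicative jitter (SD 3% and 2%) applied to
every phenotype parameter, seeded deterministically from the
(kind, identifier) pair via CRC32 so a line keeps its idiosyncrasy
across plates. Every render is a pure function of (spec, seed) through a
`SeedSequence` tree.

**What the generator does not model** — and hence what passing tests do
not establish about real data: point-spread functions and chromatic
aberration, cell motility and division, uneven illumination, plate-edge
effects, segmentation errors, and staining-batch variation beyond the
experiment random intercept.

## Preprocessing

The pipeline order is fixed: MIP → 8-bit → RGB composition →
autocontrast → tiling → resize → normalization; the composed
`preprocess_field` is tested to equal the chained single steps exactly.
Choices the upstream description leaves open:

* 16→8-bit conversion is `floor(x/256)` — content-independent, unlike
  per-image min-max scaling.
* Autocontrast operates per channel on that channel's own histogram,
  trimming 0.1% of pixels from each tail and remapping linearly; the
  lookup table reproduces Pillow's `ImageOps.autocontrast` bit-for-bit
  (tested against Pillow across cutoffs), and constant or placeholder
  channels pass through unchanged.
* Resizing is bilinear with anti-aliasing off, the dominant default in
  classifier input pipelines.
* Tiling is row-major from the top-left, 0-based.
* The sixfold augmentation order is fixed — original, 90° rotation,
  horizontal mirror, vertical mirror, rotated horizontal mirror, rotated
  vertical mirror — so dataset indices are reproducible. Augmentation is
  applied only inside training; evaluation images never pass through it.

## Classifier stack

The default backbone is a four-block stride-2 conv/ReLU CNN (widths
8-16-32-32, global average pooling, 2-way softmax head; ≈15k
parameters), implemented in numpy with im2col convolutions and exact
backpropagation to the input. Both directions are analytically exact
gradients (verified against finite differences), which is what lets the
same engine serve integrated-gradients attribution. A `linear` backbone
(one dense layer) is available for fast structural runs and for
attribution tests where a linear scorer makes the path integral exact.
A pretrained MobileNetV2 option is declared in the config surface but
raises: fine-tuning a published backbone requires a framework with
distributed weights, and the framework-free scratch CNN is the
package's deliberate desk-scale default.

Training follows the reference protocol: SGD, learning rate 0.001,
batch 32, cross-entropy, 10 epochs (recipes use 4–6 epochs at reduced
input size). Two deviations, both recorded in `ClassifierConfig`:
momentum 0.9 (a from-scratch CNN at lr 0.001 without momentum barely
moves in 10 epochs; fine-tuning a pretrained network does not have this
problem), and float32 training arithmetic (halves CPU time; float64 is
a config flag and is used in the attribution tests). One config seed
expands deterministically into weight-init and batch-order streams, so
identical data + config reproduce identical models.

**Cross-validation.** Stratified k-fold (scikit-learn) with 5 repeats
("subsets") under different shuffle seeds; the repeats are full
re-shuffles of the whole set, since no subset construction is specified
by the protocol this mirrors. The default split unit is the *field
image*: all crops of a field travel together between train and test,
preventing sibling-crop leakage; `split_level="crop"` restores the
crop-level protocol. AUC is computed on held-out crops by the midrank
formula U/(n₊n₋), tested to 1e-12 against both exhaustive pair counting
and trapezoidal ROC integration. Probabilities aggregate by arithmetic
mean: crop → field image → culture (= experiment|plate|well).

## Integrated gradients

Attributions follow the path integral of the predicted-class *logit*
(not the post-softmax probability — gradients through a saturated
softmax vanish) from a baseline to the input, discretized at segment
midpoints; the midpoint rule keeps the completeness error
|Σ attributions − (F(x) − F(x′))| well under 2% at 200 steps and is
exact for a linear scorer at any step count. The default baseline is a
pitch-black image *in intensity space* pushed through normalization,
i.e. per-slot (0 − mean)/std — with an all-zero baseline in normalized
space, dark background pixels (which sit ≈ −2σ) would receive spurious
attribution. The magnitude map is the per-pixel L1 norm over slots,
max-normalized to [0, 1] (an all-zero map stays zero); overlays blend a
white→blue ramp by magnitude. Completeness is a *relative* error, so it
is only meaningful when the score gap is away from zero; the validation
suite attributes confidently-scored images for that check.

## Inference

* **Mann–Whitney** (one-sided): exact enumeration of all C(n, n_b) rank
  assignments conditional on observed midranks for combined n ≤ 12
  (ties handled exactly); beyond that, the normal approximation with
  midrank tie correction and 0.5 continuity correction. Exact and
  approximate paths agree within 0.01 at n = 6 vs 6.
* **Mixed models**: per-culture predictions regressed on a binary
  condition with crossed random intercepts for cell line and experiment
  (statsmodels `MixedLM` with variance components; both factors enter
  one model by default, either alone via the `random=` argument). All
  fits use **ML, not REML**, because every p-value is a likelihood-ratio
  test between models differing in fixed effects, for which REML
  likelihoods are not comparable. The LRT uses χ² with df = 1 and no
  boundary correction (the tested effect is a fixed effect). If the
  L-BFGS fit of the full model lands below the reduced model's
  likelihood — an optimizer artifact that would produce a negative χ² —
  both models are refit with a wider optimizer roster and the best
  likelihood wins; a genuinely negative LRT after that raises. With a
  single level in every random factor the model collapses to OLS with a
  warning. Effect sizes are reported on the raw probability scale of
  the predictions.
* **Clustering**: Ward linkage on Euclidean distances between condition
  effect-size profiles (scipy), with dendrogram leaf order exposed for
  adjacency checks.

## Problem sizes in the validation suite

Recipes run at 540-px fields (four 270-px crops each, resized to 64 px),
50 fields per class (200 crops per class), 3 z-planes, 10-fold CV; the
transfer study uses 2 experiments × 3 lines × 4 conditions × 6 fields.
The null-calibration study uses 200 replicates of 84 cultures. These
sizes were chosen so each study completes in minutes on a single core
while keeping the recovery statistics (median AUC ordering at p < 0.01,
effect recovery within 2 SE, 5% ± 3% type-I error) comfortably resolved.
Variance-component recovery is assessed on the mean of several
5,000-culture replicates because with ~50 random-effect levels a single
realization's component estimate has ~20% sampling error regardless of
the number of cultures.

## Known limitations

* The scratch CNN at 64-px inputs detects the synthetic phenotypes at
  AUC ≈ 0.7–0.95 depending on contrast strength; it is not a statement
  about attainable AUC on real microscopy, where transfer learning from
  pretrained backbones is the appropriate tool.
* Synthetic effect sizes are design parameters; only ordering and
  compartment-localization claims transfer.
* The Mann–Whitney exact path is O(C(n, n_b)) and intentionally capped
  at combined n = 12.
* `MixedLM` variance components are ML estimates and shrink toward zero
  with few levels; with 7 lines × 3 experiments the component estimates
  are noisy even when the fixed effect is precisely recovered.
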