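# Methods

## Model and procedure

The package trains a per-pixel classifier F(x) → p̂ ∈ Δ^C on images with R
independent annotations y⁽¹⁾…y⁽ᴿ⁾ per image. The supervision target is a
*soft label*: by default each rater's one-hot map is smoothed with a
spatially varied label-smoothing (SVLS) kernel and the R smoothed maps are
averaged,

    p(i,j) = (1/R) Σᵣ (1/Σw) Σ_{a,b} y⁽ʳ⁾(i−a, j−b) · w(a,b),

with w(a,b) = exp(−(a²+b²)/2σ²), σ = 1, on a 3×3 window. Because the same
kernel is applied to every rater, smoothing the per-rater maps and then
averaging equals smoothing the average; the implementation performs the
per-rater smoothing literally. Borders are handled with replicate padding
so the normaliser Σw is constant over the image.

Rater disagreement is measured per pixel by the interclass variance
Var(p) = (1/C) Σ_c (p_c − 1/C)². It is *inversely* related to entropy:
Var is largest, (C−1)/C², at one-hot (agreed) pixels and zero at uniform
(maximally disputed) pixels. Thresholding at μ yields the asymmetric masks

    mask⁽GT⁾ = 𝟙[Var ≥ μ],      mask⁽CR⁾ = 1 + 𝟙[Var < μ],

and the training objective

    L = λ₁ ⟨mask⁽GT⁾ ⊙ ℓ_sup(p, p̂)⟩ + λ₂ ⟨mask⁽CR⁾ ⊙ ℓ_cons(F(π x), π F(x))⟩,

λ₁ = 1 − λ₂, where π is a flip drawn uniformly per batch from
{horizontal, vertical, both} and both ℓ are soft cross-entropies by
default. Supervision is withheld on uncertain pixels; the consistency
constraint applies everywhere and with double weight where supervision was
withheld.

## Interpretation choices in the mask definition

The all-ones offset in mask⁽CR⁾ is read additively (values in {1, 2}); a
diagonal-identity reading would zero the consistency loss almost
everywhere, contradicting the stated intent that consistency
regularization acts on the whole image. A `cr_mask_mode="replace"` option
provides the flat all-ones alternative.

The default hyperparameter pair is (μ, λ₂) = (0.005, 0.5). The source
material prints the pair in both orders in different places; only
μ = 0.005 is consistent with the binary variance ceiling of 0.25 (a
threshold of 0.5 could never be reached), so the table ordering is taken
as authoritative and both parameters remain independently configurable.

## Consistency-term gradients

The consistency cross-entropy −Σ t log q uses t = F(π x) (the prediction
on the flipped image) as the target and q = π F(x) as the prediction. The
formula is symmetric in the network's parameters and no stop-gradient is
specified, so by default gradients flow into *both* branches
(∂L/∂q = −t/q, ∂L/∂t = −log q); a `detach_target` flag gives the
mean-teacher-style alternative. All gradients, including the two-branch
consistency path, are verified against central finite differences in the
test suite.

## Losses and reductions

All losses reduce as means over pixels and batch rather than sums, keeping
the learning-rate scale independent of image size. The log is clamped at
1e−8; soft Dice uses smoothing 1e−5 in numerator and denominator; the
focal default is γ = 2. Soft Dice is a region-level loss, so the pixelwise
GT mask is not applied to it when it is selected as the supervised loss;
cross-entropy and focal are masked pixelwise. Ties in majority voting and
in post-dilation overlap resolution go to the lowest class index.

## Network and optimization

The segmentation network is a compact U-Net written directly in NumPy:
`depth` resolution levels of two 3×3 conv + ReLU blocks with 2×2 max
pooling, a bottleneck, nearest-neighbour upsampling with skip
concatenation, and a 1×1 softmax head. Convolutions use zero padding and
im2col matrix multiplication; backprop is hand-written and
finite-difference-verified. The network is intentionally *not*
flip-equivariant (zero padding plus asymmetric learned kernels), which is
what gives the consistency term traction.

Defaults: depth 2, 8 base channels, Adam with lr 1e−4, batch 4,
60 epochs. The desk-scale benchmark used throughout tests and the
reproduction script runs 200 synthetic 64×64 images for 15 epochs with
depth 2 / 8 base channels (~8k parameters) and lr 1e−3, which trains in
about 1.5 minutes on one CPU core; the full-scale defaults remain
available through `TrainConfig`. The higher benchmark learning rate is an
optimization-stability choice: at 1e−4 — a value appropriate for networks
three orders of magnitude larger — the tiny network lingers on an
all-background plateau for roughly half of the 15-epoch budget, and the
epoch at which it escapes dominates seed-to-seed variance. One flip is sampled per batch and shared across it; the
original and flipped half-batches share a single doubled forward/backward
pass. Training aborts with the offending batch ids if the loss becomes
non-finite. Checkpoints (parameters, Adam state, config) round-trip
bit-exactly through `ModelState.save`/`load`.

All randomness flows from integer seeds through `numpy.random.Generator`;
separate derived streams drive the train/validation split, batch
shuffling, and flip sampling, so e.g. disabling the consistency term does
not perturb the data order. Runs are bit-reproducible in single-threaded
BLAS mode.

## Synthetic data generator

Ground-truth masks are random smooth blobs (largest connected component of
thresholded Gaussian-filtered noise, ~28 % quantile foreground) alternated
with random ellipses; with C > 2 each foreground class gets its own shape
and overlaps resolve to the lower class index. Images are the class map
rendered at evenly spaced intensity levels in [0.15, 0.85], Gaussian
blurred (σ = 1) and corrupted with additive N(0, 0.08²) noise — learnable
but not pixel-trivial.

The default five-rater panel emulates archetypal annotator biases:

| rater | model | default |
|---|---|---|
| faithful | boundary jitter: eroded core plus a random half of the ±r annulus | r = 1 |
| over-segmenting | per-class dilation (disk) | r = 2 |
| under-segmenting | per-class erosion (disk) | r = 2 |
| fractured + over-segmenting | dilation then removal of straight ~1.5 px strips through the centroid at random angles | r = 2, 2 fractures |
| all-background | constant zero map | — |

Radii are calibrated visually so the five raters disagree clearly on a
~64 px structure while remaining plausible annotations; the strip geometry
of the fractures is this package's own choice. The generator emulates
*systematic* rater biases on clean shapes; it does not model
image-dependent difficulty (e.g. occlusions), rater correlation, or
anatomy-specific boundary ambiguity, so passing tests demonstrate the
machinery's correctness and the method's behaviour under controlled bias,
not clinical performance.

## Fusion baselines

Binary STAPLE is the standard EM that alternates a per-pixel consensus
posterior with per-rater sensitivity/specificity estimates; initialisation
is sensitivity = specificity = 0.99999 with a scalar foreground prior
equal to the mean rater foreground fraction, stopping when parameter
changes fall below 1e−7 (multiclass STAPLE is out of scope). GLS uses
ε = 0.1 by default. Sharpening exponentiates by 1/T and renormalises.

## Evaluation

DSC = 2TP/(2TP+FP+FN) and IoU = TP/(TP+FP+FN) are computed one-vs-rest
per class; the background class is excluded from the reported means by
default, and an empty-vs-empty class scores 1 by convention. Soft
multithreshold scores binarize prediction and soft reference at
{0.1, 0.3, 0.5, 0.7, 0.9} and average the per-threshold scores. Aggregates
are computed per image and then averaged. Validation during training uses
the synthetic ground truth; with real data and no ground truth the
majority vote of the raters (the silver standard) is the intended
reference.

## Known limitations

- On the desk-scale benchmark the plain soft-label baseline can outscore
  the full method at matched epochs. Two structural reasons: (i) the
  simulated panel's biases are *symmetric* around the true boundary
  (dilation radius 2 vs erosion radius 2), so the averaged soft label is
  maximally informative exactly at the uncertain boundary pixels that the
  asymmetric mask withholds from supervision — the setting the masking is
  designed for is one where disagreement marks *unreliable* annotation,
  not annotation that is noisy but unbiased; and (ii) λ₁ = 0.5 halves the
  supervised gradient, slowing convergence within a short epoch budget.
  The benchmark comparison is therefore a matched-epoch direction check
  under these particular simulated conditions, not an effect-size estimate
  for real multirater data.
- Only 2-D inputs, binary STAPLE, and flip (not rotation) consistency are
  implemented.
- The NumPy trainer is single-threaded-deterministic and CPU-oriented; it
  is not intended for large images or deep encoders.
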