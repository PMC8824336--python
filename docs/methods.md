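# Methods

## Problem setting

`frugalseg` trains multi-class semantic segmentation networks on
*heterogeneously labeled* data: datasets in which different samples carry
ground-truth masks for different subsets of the classes.  A sample is a
triple `(x, ỹ, m)` — an RGB image `x` of shape `(h, w, 3)`, a binary
ground-truth tensor `ỹ` of shape `(h, w, C)` with one channel per class
(background included as the last channel), and a binary mask vector
`m ∈ {0,1}^C` flagging which classes actually have a mask for this sample.
The motivating application is segmentation of the three chambers of the
medaka fish heart (atrium, ventricle, bulbus) in ventral-view microscopy
images, where annotating one mask takes ~25 s and datasets are routinely
only partially annotated.

## The combined objective

Two loss terms complement each other:

**Mask-weighted Dice loss.**  The soft Dice–Sørensen coefficient of
channel `c` is

    DSC_c = (2 Σ_uv ỹ_uvc ŷ_uvc + ε) / (Σ_uv ỹ_uvc + Σ_uv ŷ_uvc + ε),

with `ε = 1e-7` in both numerator and denominator so empty-vs-empty
channels score 1 and nothing divides by zero.  The loss averages `1 − DSC`
over the *labeled* channels only:

    L_DSC = Σ_c m_c (1 − DSC_c) / Σ_c m_c .

Missing masks contribute neither signal nor noise; a sample with no
labeled channel at all is rejected (0/0), never silently scored 0.

**Class-asymmetric loss.**  Segmentation classes are mutually exclusive:
a pixel with a ground-truth class cannot belong to any *unlabeled* class.
For a labeled class `c`,

    CAL_c = Σ_uv ỹ_uvc · Σ_{z≠c} f(ŷ_uvz) (1 − m_z),

with `f` the logistic sigmoid, and `L_CAL = Σ_c m_c CAL_c` over the
labeled, non-background classes.  The background channel is excluded from
both sums (outer `c` and inner `z`): a background channel defined as the
complement of the labeled foreground cannot be distinguished from
"unlabeled", so it must not drive or receive the asymmetric penalty.

The combined objective is

    L = (1 − α) L_DSC + α L_CAL,   α ∈ [0, 1);

`α = 1` is rejected because `L_CAL` constrains only unlabeled channels and
cannot drive training alone.

### Numerical notes on L_CAL

* `f = sigmoid` maps 0 to 0.5, so even zero predicted mass in an unlabeled
  channel contributes a constant 0.5 per labeled pixel.  The constant has
  zero gradient only where `f' ≈ const`; it is kept as the reference
  semantics (an `identity` activation is also available).
* As written, `CAL_c` is an **unnormalised pixel-count sum**: on a 64×64
  image it reaches hundreds while `L_DSC < 1`.  With that scale any
  `α ≳ 0.01` makes the asymmetric term dominate the gradient completely —
  effectively `α ≈ 1`, exactly the regime the definition declares invalid —
  and in our training runs it collapses the labeled classes.
  `LossConfig(normalize_cal=True)` divides `CAL` by `w·h`, making the two
  terms comparable so `α` interpolates meaningfully; the evaluator default
  is the literal sum (fidelity first), but the experiment harness uses the
  normalised scale, without which a mid-range optimum for `α` such as the
  one the method reports cannot exist.
* Loss gradients are taken with respect to the prediction array the loss
  consumes (per-channel values), where the masking statements are exact:
  at `α = 0` the gradient on unlabeled channels is identically zero.
  Through a softmax head all channels couple, so the statement holds at
  the loss boundary, not through the coupling.

## Evaluation metrics

Test-set predictions are binarised by per-pixel argmax (ties to the lowest
class index) before scoring per-class DSC and IoU; `mDSC`/`mIoU` average
over the foreground classes, with the background reported separately.  The
**Performance Frugality Ratio** `PFR(M) = M / n` divides a statistic `M`
by the number of available training labels `n = S − P` (sample–label
pairs minus dropped ones), rewarding performance achieved with fewer
labels: halving `n` at equal `M` doubles the ratio.

## Heterogeneous label generation

`hetgen` turns a homogeneous dataset into a partially labeled one without
touching the source: for each class in the eligible set `d`, exactly
`P = round(ρ·S)` of the `S` samples lose that class's mask
(round-half-away-from-zero when `ρ·S` is fractional; draws independent
across classes, fully determined by `(seed, epoch, class)`).  Labels are
dropped online at access time; a per-iteration *sample memory* records the
realised flags on first access so oversampled re-queries within one
iteration are bit-identical.  Two persistence modes:

* `per_epoch` — memory cleared and plan redrawn at each epoch boundary
  (the online-generator reading of "emptied after one training
  iteration");
* `whole_training` — the plan is a pure function of the seed; reset is a
  no-op.  The experiment harness uses this mode: it models a fixed
  partially-annotated dataset.

When a foreground mask is dropped, its channel is zeroed, `m_c = 0`, and
the background channel is **recomputed as the complement of the union of
the present foreground masks** (`m_background = 1`).  This deliberately
reproduces the pathology of the naive background definition — dropped
foreground pixels are silently labeled background, which is what makes
high drop shares collapse training toward the background class and what
the asymmetric loss partially counteracts.  A `strict_background` mode
instead sets `m_background = 0` whenever any foreground mask is missing.
The loss must always consult `m`; an all-zero channel is not evidence of a
missing label (real images can genuinely lack a structure).

## Network and training

A symmetric fully convolutional encoder–decoder with skip connections:
each encoder stage is two 3×3 convolutions (instance-normalised, ReLU)
followed by 2×2 max pooling; the decoder mirrors it with nearest-neighbour
upsampling and concatenation of the same-resolution encoder features; a
1×1 convolution plus per-pixel softmax yields a class simplex at every
pixel ('same' padding throughout, so output size equals input size).  The
full-scale configuration (depth 4, 64 base filters) has ~3.1×10⁷
parameters; all tests and experiments use a tiny configuration (depth 2,
8 base filters, ~3×10⁴ parameters) on 64×64 inputs.

The network and its training loop are implemented directly on NumPy
(`frugalseg.nn`): convolution as nine offset matrix products, hand-written
backward passes, and Adam (lr 1e-3).  Instance normalisation (per sample
and channel over the spatial axes) is load-bearing, not cosmetic: without
it feature magnitudes grow ~5× per stage, the softmax saturates, and the
overlap-based losses — whose gradients vanish through a saturated softmax,
unlike cross-entropy — freeze with most classes dead.  It is batch-size
independent and identical at train and inference time.

Training minimises the combined objective per sample (each sample keeps
its own `m`, so the `Σ m_c` normalisation stays correct in mixed batches)
averaged over batches of 8–11, with early stopping on the *masked Dice
loss* of a held-out 10 % validation split (patience 3–5, best weights
restored).  Conv biases are retained although instance normalisation gives
them exactly zero gradient.

## Synthetic benchmark

The generator emulates the three-chamber anatomy at desk scale: per
sample, one filled ellipse per foreground class with a distinct base
colour on a dark background, centres on a jittered chain so the regions
are adjacent but pairwise disjoint (placement retried up to 100 times),
plus additive Gaussian intensity noise (σ = 0.05) and a final background
channel as complement.  The third class is smaller and thinner ("hardest
class" analogue).  Defaults: 200 samples of 64×64, 3 foreground classes,
20 % test split.  A nearest-base-colour classifier already reaches
mDSC > 0.95 on noise-free data, which guards that the benchmark is
learnable and the metric pipeline sane.

What the benchmark deliberately does **not** model: texture, illumination
variation, soft boundaries, temporal correlation between frames, or
ambiguous anatomy.  Passing trends here show the objective and generator
machinery behave as designed, not that any particular real-data score is
reproduced.

## Experiment harness

Four desk-scale designs (tiny network, batch 8, ≤10 epochs with early
stopping, α = 0.4 for the first three, pixel-mean CAL):

1. **Ablation** — all foreground classes lose a share ρ of their labels;
   ρ = 0 is the supervised baseline.  High ρ collapses performance toward
   the background class (the recomputed-background pathology above).
2. **Transfer** — the "ventricle" class stays fully labeled while the
   "atrium" class's labels shrink; the retained class is expected to stay
   stable across the sweep.
3. **Merge** — the training set is split into two parts at a proportion
   `p`, each part keeps exactly one class's labels, and an equal-rate
   sampler oversamples the minority side (with replacement, to the
   majority count) every epoch.
4. **Alpha sweep** — the transfer setup at ρ = 0.5 across α values,
   separating the contributions of the two loss terms.

Statistics are computed on the fully labeled test split only; every row of
the result table carries its run seed, and aggregates are mean/std over
the configured run count (3 by default).  The problem sizes (200 images,
64×64, ≤10 epochs, 1–3 runs per configuration) are the package's
desk-scale protocol; sweeps and run counts are flags.

## Known limitations

* The NumPy training loop is CPU-bound and desk-scale by design; it makes
  no attempt at GPU-scale reproduction of full-resolution results.
* Augmentation (tiny rotations/shears, shifts, zoom in [1−z, 1+z],
  horizontal flips, nearest fill, resize to 256×256) is implemented in
  `data_io` and used for real-image pipelines; the synthetic experiments
  skip it — the generator already randomises geometry, and the fixed-view
  imaging it emulates leaves little useful augmentation headroom.
* Per-class label drops are independent, so a sample can lose all its
  foreground labels; with the recomputed background it remains usable
  (background-only supervision), under `strict_background` it would be
  skipped.
* `PFR` compares runs only at equal statistic scale and dataset size; it
  is a ratio, not a calibrated trade-off model.
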