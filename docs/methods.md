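# Methods

## The augmentation search space

The package implements a low-cost augmentation policy search for
class-imbalanced medical image classification. The search space is an
unordered set of 12 *subpolicies*, each pairing one color transform with one
geometric transform. There are 12 distinct color operations (brightness,
contrast, saturation, hue shift, channel jitter, Gaussian noise, sharpness,
posterize, solarize, equalize, autocontrast, gamma) and 6 geometric
operations (horizontal/vertical flip, rotation, scale, translation, shear);
each geometric operation appears in exactly two subpolicies so both families
have the same marginal selection probability.

During training, one subpolicy is drawn uniformly per image and each of its
two operations executes independently with a single probability `P`, the
only searched hyperparameter. `P` ranges over the ladder
{0.1, 0.3, 0.5, 0.7, 0.9}, giving 12 × 5 = 60 (subpolicy, probability)
combinations — a search space of order 10¹, versus 10³²⁺ for learned-policy
searches. Executed operations draw their magnitude uniformly from the
op-specific range on every execution.

Choices the source protocol leaves open, fixed here:

* **Magnitude ranges** follow common learned-augmentation practice: rotation
  ±30°, translation ≤0.2 of the side, shear ≤0.3 rad, scale 0.8–1.2,
  brightness/contrast/saturation factors 0.6–1.4, hue offset ±0.1, noise
  σ ≤ 20/255. All are configurable through the YAML space schema, so a
  user with a preferred table can substitute it.
* **Execution semantics**: "the execution probability of the two operations
  is the same" is read as *independent* execution of each op with
  probability `P` (both-or-neither is the obvious alternative; independent
  execution keeps the two op families exactly equally likely while producing
  a richer mix of outcomes). The color op is applied before the geometric
  op; the order is arbitrary but fixed for reproducibility.
* **Frame preservation**: rotation, translation and shear fill exposed
  pixels by edge reflection; scale crops or reflect-pads back to the
  original frame. This keeps downstream crop geometry valid for every image.
* Pixel values are clipped into the valid range after every operation;
  8-bit images round-trip through float in [0, 1].

## Two-stage search

**Stage 1 (augmentation search).** For every candidate probability and every
candidate backbone, models are trained with grouped 5-fold cross-validation:
lesions (groups) are shuffled with a seeded RNG and greedily assigned to the
lightest fold, so all images of one lesion stay on one side of every split
and fold sizes balance to the 4:1 ratio. The screening criterion for a
candidate is the mean over folds of the *best* validation balanced accuracy
across scored epoch checkpoints. The selected probability is the one
preferred by the majority of backbones' per-backbone argmax, ties broken by
the higher mean criterion.

**Stage 2 (network match).** Every backbone is retrained on the full
training set with the selected strategy and scored on a grouped held-out
test set by multi-crop averaged predictions at each checkpoint; the backbone
with the best test balanced accuracy is recommended.

The training protocol per epoch: augment each image by the strategy, then
take a random crop of the configured input size; optimize the weighted
cross-entropy with Adam under a step schedule — learning rate 1e-3, divided
by 10 after 20 epochs and again every 10 epochs, 70 epochs total at the full
protocol. Class weights are the inverse normalized class frequencies
`w_i = N / n_i`, computed on the training split only (never the validation
split, to avoid leakage) and left unnormalized. The per-batch loss is
`L = −Σ_i w_i p_i log p̂_i` averaged over the batch (mean reduction;
configurable to sum); the log is clamped at 1e-12.

## Metrics

All per-class metrics are one-vs-rest ratios of confusion counts: precision
TP/(TP+FP), sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy
(TP+TN)/total. Balanced accuracy (BACC) is the unweighted mean of per-class
sensitivities. Ratios with a zero denominator are reported as missing (NaN)
and excluded from macro averages with a warning — small synthetic folds can
lack a class, and silently coercing 0/0 to zero would bias the averages.
AUC is the rank-based Mann–Whitney U statistic normalized by n₊·n₋ (ties
counted ½), which equals the trapezoidal area under the ROC curve;
multiclass AUC is the unweighted one-vs-rest macro average. "Average
precision" is macro precision from the confusion ratios, not the PR-curve
summary.

## Multi-crop evaluation

At test time, n × n regions of interest of the model's input size (default
16 crops of 224×224) are cropped with top-left offsets at
`round(linspace(0, side − crop, n))` along each axis — the unique simple
reading of "equidistant from the upper-left to the lower-right corner" —
and the per-crop *probabilities* (not logits) are averaged, keeping the
output a convex combination of distributions. Images are not rescaled
before cropping.

## Grad-CAM++

For a target class score `Z` and last-conv feature maps `A^k`, the
pixel-wise gradient weights are
`α = ∂²Z / (2 ∂²Z + Σ A ∂³Z)`, the channel weights
`w_k = Σ α · relu(∂Z/∂A)`, and the heatmap `L = relu(Σ_k w_k A^k)`.
Where the α denominator is smaller than 1e-8 in magnitude it is replaced by
1, so α degrades to 0 when the numerator also vanishes (a score exactly
linear in the feature maps). Normalization of the heatmap is min–max to
[0, 1]; an all-constant map normalizes to zeros to avoid 0/0. Overlays use
bilinear upsampling.

How the derivative tensors are produced is the backbone's concern. The
reference CNN's head is linear in the feature maps, so the raw score has
vanishing higher derivatives; it therefore differentiates the exponential of
the score, whose derivatives are `S·g`, `S·g²`, `S·g³` with `g` the linear
gradient map — the standard closed form for pooled linear heads. `S` is
evaluated as `exp(Z − max Z)`, a positive rescale that leaves α and the
normalized heatmap unchanged but cannot overflow.

## Reference backbone

A deliberately tiny NumPy CNN: two stride-2 3×3 convolutions (8 and 16
channels, ReLU), 2×2 average pooling, and a linear head over the flattened
pooled maps, trained with Adam. Inputs are centered (−0.5 after scaling to
[0, 1]); all-positive inputs condition the first layer badly and cost
several epochs of plateau at desk scale. The head's dimension depends on
the input size and is created lazily at the first forward pass, so a
trained model expects fixed-size crops — which the pipeline always feeds.
The backbone contract (batch probabilities, a single Adam `train_step`, and
a Grad-CAM++ `feature_stack`) is what any pluggable replacement must
implement; analytic gradients are verified against central finite
differences in the test suite.

## Synthetic data

The generator renders a skin-tone background with a mild illumination
gradient, one centered elliptical lesion whose border is perturbed by three
sinusoidal harmonics (the irregularity amplitude), multiplicative speckle
texture, and additive Gaussian pixel noise. Class signals live in the
lesion's hue/saturation and its eccentricity/irregularity. The default
dataset mirrors the 7-class imbalance of the HAM10000 archive (6705 nevi
down to 115 dermatofibromas) rescaled to 700 images by largest-remainder
rounding, so weighted-loss effects are visible at desk scale. Lesions can be
re-imaged: images of one lesion share geometry, color and illumination up to
a small jitter and carry a group id for grouped cross-validation.

Two planted-invariance variants support recovery experiments:

* **color-nuisance** — class is carried purely by shape (eccentricity ×
  irregularity at extreme levels); hue is random per lesion. A hue readout
  scores at chance while an eccentricity threshold separates the
  smooth-border classes; both facts are asserted in the tests.
* **shape-nuisance** — class is the lesion pigment hue (4 hues 0.25 apart);
  shape and pose are random per lesion, and each lesion carries a random
  per-channel illumination color cast in [0.65, 1.35], shared by all its
  images. The cast is the planted nuisance: a network trained without
  augmentation memorizes its training lesions' casts and misreads the
  pigment of unseen lesions, while photometric augmentation (brightness,
  saturation, channel jitter) simulates new casts and restores
  generalization.

What the generator does **not** emulate: hair, rulers, gel bubbles,
vignetting, realistic lesion texture, multiple lesions, or annotation noise.
Passing tests therefore demonstrate that the pipeline's machinery behaves as
specified on data with known structure — not that any particular
augmentation policy transfers to real dermoscopy.

## The recovery experiment

The end-to-end check that stage 1 finds a genuinely planted optimum runs at
desk scale: shape-nuisance data with 4 classes, n=400 at 64×64, a tiny CNN,
grouped 5-fold cross-validation, 10 epochs per fold, and a two-arm ladder
{0.01, 0.3} — a near-zero probability versus a clearly nonzero one (an
exact 0 is outside the ladder's domain; at P=0.01 an op executes on ~1% of
images). A repeat succeeds when the nonzero arm is selected; the experiment
reports successes over 10 independently seeded repeats.

Protocol choices for this scale, fixed once: learning rate 5e-3 (the tiny
from-scratch CNN needs it to converge within 10 epochs; the full protocol's
1e-3 schedule is tuned to large pretrained backbones over 70 epochs), 56×56
random crops, 2×2 evaluation crops, batch 32, and checkpoint scoring from
epoch 5 onward — mirroring the full protocol's practice of scoring only the
later part of the schedule, where the augmentation effect rather than
early-training noise dominates the best-checkpoint statistic.

Why this variant: with a two-convolution network and a 10-epoch budget,
shape classes are still underfitted when training ends, and stochastic
augmentation only slows convergence — no augmentation probability can win.
The pigment-hue classes are learned within a few epochs, after which the
cast nuisance dominates validation error, which is exactly the regime where
augmentation pays. This mirrors the practical observation that augmentation
search needs the base task to be within the model's reach.

## Numerical and degenerate-input conventions

* Softmax is max-shifted; non-finite logits are rejected.
* log clamp ε = 1e-12; α-denominator guard 1e-8.
* Probability rows must sum to 1 within 1e-6 before multi-crop averaging.
* Undefined metric ratios: missing, excluded from macro averages, warned.
* A single master seed fans out into named substreams (folds, per-fold
  init, augmentation) via CRC-keyed `SeedSequence`s, so the full two-stage
  report is byte-reproducible and individual stages are independently
  reproducible.
* Ties in fold assignment go to the lowest fold index; ties in the
  probability vote are broken by the higher mean criterion.

## Problem sizes used by the shipped checks

Oracle comparisons use 1,000 random batches (loss), 1,000 random confusion
settings and 200 score sets (metrics); sampling laws use 120,000 subpolicy
draws and 40,000 executor calls; the recovery experiment uses 10 repeats of
the 5-fold search at n=400; byte-reproducibility runs a reduced two-stage
search (n=160, k=2, 2 epochs) twice. These sizes were chosen so the whole
suite runs on one desktop CPU core in minutes while keeping binomial/χ²
test power high.

## Known limitations

* The shipped backbone is far below the capacity regime of the full
  protocol; stage-1 selections at desk scale need not transfer upward.
* The op roster and magnitude table are a documented reconstruction, not
  the original table; results depend on them only through the YAML config.
* Grad-CAM++ heatmap quality is only as good as the backbone; with the
  tiny reference CNN the maps are coarse (last-conv resolution is ~1/4 of
  the crop side).
* The AUC macro average skips classes absent from the evaluated sample
  rather than imputing them.
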