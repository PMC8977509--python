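# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the synthetic fixture, and the numerical and
design choices made where the design was genuinely open.

## Forward model

Networks are stacks of bias-free layers: 3×3 convolutions ("same" padding
of 1 so only pooling downsamples), non-overlapping max/average pooling,
flatten, and linear maps. Hidden layers apply `hardtanh` (clipped to
[−1, 1]) or `tanh`; the top layer — the 64-dimensional linear projection
head in all shipped configs — applies no nonlinearity. The forward
computation is `x_l = σ(W_l x_{l−1})` with all activations cached per
batch, because every training rule here consumes cached pre- and
post-activations rather than a graph.

Parameters initialise uniformly in ±1/√fan-in. Each trainable layer also
owns a feedback block `B_l` of the transposed linearised shape, drawn
independently from the same distribution (a separate RNG stream of the
same seed), used by the random-feedback rules. Images are channel-first
float arrays in [0, 1]. Max-pool ties break on the first (row-major)
index so traces are bit-reproducible; that recorded argmax is also where
pooled error routes on the way down (average pooling spreads uniformly).
`hardtanh`'s derivative is the 0/1 indicator of the open interval (−1, 1).

## Contrastive hinge loss

For a batch of n positive pairs with per-anchor negative sets N_s of size
T taken from the deformed B branch:

    L = Σ_s [‖x_s^A − x_s^B‖₁ − m1]₊ + Σ_s Σ_{t∈N_s} [m2 − ‖x_s^A − x_t^B‖₁]₊

The per-batch loss is a sum, not a mean; learning-rate presets account
for this. The error signals are the exact (sub)gradients — products of
0/1 distance indicators and coordinate-wise signs — with `sgn(0) = 0` and
strict inequalities in the indicators, so at a hinge boundary both the
indicator and the hinge term vanish and loss and gradient stay
consistent. Gradient blocking (default on) drops the anchor-branch term
from all updates: the anchor embedding functions as a short-term memory
trace. Negatives default to T = 5.

**Temporal negatives.** "Closest in time" is realised as cyclic batch
order: anchor s gets negatives s+1 … s+T (mod n). With T = 1 each index
serves as a negative exactly once. Negatives are taken from the deformed
B branch (the same tensors whose embeddings receive positive-pair
updates), so each B embedding accumulates its positive-partner signal
plus every signal it receives while serving as a negative.

**Margins.** The named presets carry the published values (m1 = 1, m2 = 3
for 32×32 colour images; m1 = 1, m2 = 1.5 for 28×28 grayscale). Margins
are meaningful only relative to the initial distance scale of the
embedding they gate, so the package also ships the histogram diagnostic
that derives them: m1 at the 0.1 quantile of the initial positive
distances, m2 at the 0.9 quantile of the initial negative distances,
bracketing both distributions so optimisation starts with most pairs
active. The desk-scale experiments use this calibration — and apply it
per stage in layer-wise training, because each auxiliary head spans its
own embedding space with its own distance scale (with shared margins the
first stage, whose positive and negative distributions overlap most, can
drift into an expansion regime where the positive hinge grows without
bound).

**SimCLR baseline.** The normalised-temperature cross-entropy over cosine
similarities is implemented as an evaluation-only scalar (log-sum-exp
stabilised; for each anchor the denominator excludes only the anchor's own
view, the standard convention). There is no SimCLR training path: the
package's training mechanisms are built around the hinge loss, whose
error signals are closed-form.

## Credit assignment

* **BP** (reference): δ_l = σ′(h_l) ⊙ W_{l+1}ᵀ δ_{l+1}; weight gradients
  are Hebbian products δ_l x_{l−1}ᵀ accumulated over the contributing
  branches.
* **RF**: the transpose is replaced by the fixed feedback block B_{l+1},
  drawn once at build time and frozen.
* **URF**: B receives exactly the increment the optimizer applies to W
  (transposed for linear layers), applied simultaneously in the same
  step. By induction, initialising B = Wᵀ makes URF identical to BP at
  every step, for SGD and Adam alike — a property the tests assert to
  float tolerance over 100 steps.
* **DTP**, below.

The update equations are plain gradient descent; the experiments use an
Adam preset (β = 0.9/0.999) because it makes step sizes insensitive to
the loss's sum scaling, with SGD available everywhere as the reference
rule.

## Difference target propagation

Stages group each convolution with its adjacent pooling layers; the
flatten + linear head is the top stage. Stages from the second upward own
inverses: a transposed convolution whose stride matches the stage's
downsampling (kernel 4, stride 2, padding 1 under 2× pooling; kernel 3,
stride 1 otherwise — realised as the exact adjoint of a virtual forward
convolution onto the stage's input shape, which guarantees shape
agreement for any input size including odd ones), or a linear map for
flat stages. One step per batch: (1) forward; (2) one SGD step per
inverse on ‖g_l(f_l(x_{l−1})) − x_{l−1}‖²/n computed on clean activations
(no noise injection); (3) targets, x̂_L = x_L − η_L ∂L/∂x_L at the top and
x̂_{l−1} = x_{l−1} + (g_l(x̂_l) − g_l(x_l)) below — the correction is
computed as a difference first so the zero-gradient fixed point
(targets ≡ activations, local losses exactly 0) holds bitwise; (4) one
step per forward stage on ‖f_l(x_{l−1}) − x̂_l‖²/n (the top stage descends
the global loss). η_L defaults to the forward learning rate. Stage
updates provably read no forward weights above their own stage; the test
suite asserts this through parameter-access tracing.

With gradient blocking, inverse training, targets and forward updates all
run on the B-branch trace; without it the anchor trace receives its own
target pass and updates as well.

## Layer-wise training

Auxiliary heads are flatten + linear maps to the 64-d embedding space,
one per conv stage, initialised like every other layer and equipped with
their own feedback blocks. Training a stage is single-hidden-layer
learning: the frozen layers below provide inputs, the loss is computed
above the stage's head, and the one-layer error propagation uses BP, RF
or URF. GLL trains stages bottom-to-top on a fixed step budget each; RLL
draws the stage uniformly per batch (literally per batch, not per epoch)
and forwards through the layers below at their current, continuously
updated values. Heads of finished GLL stages are discarded — evaluation
attaches a fresh linear classifier. Exactly one stage and its head change
per step; the isolation tests assert this by checksumming every other
block.

## Deformations

Positive views apply, in fixed order: square random resized crop (area
fraction uniform in the scale range, bilinear resize), horizontal flip,
colour jitter (brightness and contrast for all images; saturation and a
YIQ-plane hue rotation for RGB only), random grayscale. Defaults for
colour images follow the common contrastive-augmentation settings (scale
[0.2, 1.0], jitter 0.4/0.4/0.4/0.1, grayscale 0.1, flip 0.5); the
jitter order is fixed for reproducibility. Test-time affine deformations
(rotation ±25°, translation ±15%, shear ±10° as presets) use bilinear
interpolation and zero fill. All draws derive from explicit seeds;
deformations never touch labels.

## Synthetic fixture

The default dataset: 4 classes (horizontal bars, vertical bars, ring,
cross), 28×28, 1 channel, 500 images per class, stratified 80/20 split.
Nuisances per image: centre jitter ±1 px, scale ×[0.8, 1.2], intensity
×[0.5, 1.0], Gaussian pixel noise σ = 0.08. Class identity is carried by
global shape, so every deformation family preserves labels by
construction. The small position jitter is deliberate: test-time
translations (±15% ≈ ±4 px) then lie outside the labeled training
distribution, which is the regime the robustness protocol probes. Eight
shape families exist so the encoder-on-X / probe-on-Y transfer protocol
can use disjoint class sets.

What the fixture does not emulate: natural image statistics, clutter,
object pose in 3D, or fine-grained class boundaries. Desk-scale results
establish that the mechanisms optimise their objectives and preserve the
qualitative orderings; they say nothing about accuracies on natural image
benchmarks.

## Evaluation protocols and desk-scale experiment sizes

Linear probes are single linear softmax layers on the flattened output of
the last conv block (head removed, encoder frozen and checksum-verified),
trained with Adam at 1e-3 for 30–40 epochs; the supervised baseline is
the same architecture with the head width set to the class count, trained
end-to-end with BP on softmax cross-entropy under identical classifier
hyperparameters.

The reference experiments (module `biossl.experiments`) use a 3-stage
encoder (16/32/64 channels, max-pool 2 + tanh per stage, 64-d head) on
28×28 inputs, batches of 32 pairs, T = 5 blocked negatives, calibrated
margins, Adam at 1e-3 — except random feedback, which runs at 3e-4
end-to-end and 5e-4 layer-wise (misaligned updates amplify at larger
steps), and the DTP inverses, which run at 3e-3 (more faithful inverses,
hence better targets, within a 200-step budget; the fixed 1e-3 remains
the library default). Convergence runs are 200 steps per trainer × rule
combination; the representation experiment pretrains for 400 steps on the
full unlabeled training split and gives all classifiers a 25-per-class
labeled subset — robust embeddings matter most when labels are scarce —
with the deformed test set drawn from the crop/jitter family (seen by the
encoder during unlabeled pretraining, never by any classifier's labeled
data).

## Known limitations

* Pure-NumPy convolutions are single-threaded BLAS products; the shipped
  full-size configs build and run but are not meant for dataset-scale
  training.
* The SSL-vs-supervised robustness margin on the synthetic fixture is
  small (both classifiers operate near ceiling even on deformed data);
  the trained-vs-random encoder gap is the more robust ordering.
* RLL/GLL with RF inherit feedback alignment's sensitivity to step size;
  presets are conservative.
* The approximate VGG6 config is a best-effort stand-in, labeled as such.
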