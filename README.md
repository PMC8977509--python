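# biossl

Biologically plausible training mechanisms for self-supervised learning
(SSL) in small convolutional networks, implemented end to end in NumPy.

## The problem

Contrastive SSL learns image embeddings from unlabeled data by pulling two
deformed views of the same image together and pushing views of different
images apart. As a model of learning in visual cortex, the standard recipe
fails on three counts: the popular losses (e.g. the normalised-temperature
cross-entropy) require normalisation, inner products and divisions that are
hard to realise in neural circuits; backpropagation requires feedback
connections that mirror the feed-forward synapses exactly; and end-to-end
training locks every layer until a full forward/backward sweep completes.
This package implements a family of mechanisms that remove those
objections while remaining trainable, and the evaluation protocols that
measure what the learned embeddings are worth.

## What is implemented

**Contrastive hinge loss.** For embeddings $x^A_s, x^B_s$ of two views of
image $s$ and negative sets $N_s$ drawn from the B branch,

$$L = \sum_s \Big[\lVert x^A_s - x^B_s\rVert_1 - m_1\Big]_+ +
\sum_s \sum_{t\in N_s} \Big[m_2 - \lVert x^A_s - x^B_t\rVert_1\Big]_+ .$$

Its gradient w.r.t. each embedding coordinate is an integer sum of signs
gated by scalar distance indicators, so the top-layer update is a plain
Hebbian product $\Delta W_{L,ij} \propto -\delta_{L,i}\,x_{L-1,j}$ — no
normalisation anywhere. With *gradient blocking* the anchor branch
contributes no update: the anchor embedding is a short-term memory trace
that only shapes the error signal. Negatives are the $T$ batch items
cyclically following each anchor (the closest observations in time when
the batch is read as a stream). The SimCLR loss is included as an
evaluation-only baseline.

**Credit assignment.** Four interchangeable schemes:

* **BP** — reference backpropagation, $\delta_l = \sigma'(h_l)\,W_{l+1}^T\delta_{l+1}$;
* **RF** — random feedback (feedback alignment): $W_{l+1}^T$ replaced by a
  fixed random matrix $B_{l+1}$;
* **URF** — updated random feedback: $B$ starts random but receives the
  same increments as the forward weights (equal to BP under symmetric
  initialisation, exactly);
* **DTP** — single-step difference target propagation with pooling kept in
  the forward stages and learned strided-deconvolution inverses, trained
  as per-stage autoencoders; each stage descends a purely local target
  loss and never reads the weights above it.

**Trainers.** End-to-end (E2E), greedy layer-wise (GLL: one conv stage +
auxiliary projection head at a time, bottom to top) and randomized
layer-wise (RLL: a uniformly drawn stage per batch), each combinable with
BP/RF/URF; DTP is its own trainer.

**Evaluation.** Linear probes on frozen embeddings (projection head
removed), a deformation-robustness protocol (probe trained on undeformed
labels, tested on a deformed test set, paired with a supervised baseline
of the same architecture), and a histogram diagnostic that derives the
hinge margins $m_1, m_2$ from the initial positive/negative distance
distributions.

**Synthetic data.** A generator of labeled shape images (bars, rings,
crosses, ...) with controlled position/scale/intensity nuisances, so every
training and evaluation path runs in minutes on one CPU with no downloads.

## Worked example

```
$ biossl generate-data --out data --classes 4 --per-class 50 --seed 3
wrote 200 images to data

$ biossl pretrain --data data --out ckpt.npz --steps 30 --seed 3
trained e2e/bp for 30 steps in 1s; first/last loss 88.70/48.16; checkpoint at ckpt.npz

$ biossl evaluate --checkpoint ckpt.npz --data data --out eval.json --seed 3
probe accuracy 1.0000; report at eval.json

$ biossl robustness --checkpoint ckpt.npz --data data --out rob.json --seed 3
probe 1.0000, deformed 0.9750, supervised-deformed 1.0000; report at rob.json
```

The pretrain step trains the desk-scale encoder (three conv/max-pool/tanh
stages, 64-d projection head) end to end with blocked gradients: the
contrastive hinge loss falls from 88.7 to 48.2 in 30 batches. The probe
then reaches 100% on the easy 4-class plain test set — as expected, the
interesting number is the deformed-test accuracy (97.5% here), where
encoders differ. Checkpoints carry a JSON manifest (architecture, seeds,
full run config), per-step losses go to an append-only CSV, and reports
are JSON. Named presets (`cifar-hinge-gll`, `mnist-hinge-e2e`, ...) mirror
the published hyperparameters for externally supplied datasets; trainer ×
rule combinations that make no sense (DTP with RF) are rejected at config
time.

Library use without the CLI:

```python
from biossl import (SyntheticDatasetSpec, generate, build_network,
                    HingeLossConfig, FeedbackState, view_stream, train_e2e)
from biossl.presets import network_config
from biossl.deformations import DeformationConfig

ds = generate(SyntheticDatasetSpec(seed=0))
net = build_network(network_config("synth_small"), seed=0)
stream = view_stream(ds.train[0], 32, DeformationConfig(crop_size=28, seed=1),
                     n_negatives=5, seed=2)
history = train_e2e(net, stream, steps=200,
                    loss_cfg=HingeLossConfig(m1=1.0, m2=1.5, T=5),
                    fb=FeedbackState(rule="BP", learning_rate=1e-3,
                                     optimizer="adam"))
```

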