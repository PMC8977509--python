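"""Linear-probe evaluation of frozen embeddings and the
deformation-robustness protocol.

Representational quality is measured by training a single linear softmax
classifier on the flattened output of the encoder's last convolutional
block (projection head removed, encoder frozen) and reporting held-out
accuracy. Robustness is the same probe, trained on undeformed data, tested
on a deformed copy of the test set; it is paired with a supervised
baseline — the same architecture trained end-to-end on the labeled set —
so the comparison isolates the representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import feedback
from .model_core import Network, build_network, embed


@dataclass
class ProbeConfig:
    lr: float = 1e-3
    optimizer: str = "adam"
    epochs: int = 40
    batch_size: int = 64
    seed: int = 0


@dataclass
class EvalReport:
    probe_accuracy: float
    robustness_accuracy: float | None = None
    supervised_accuracy: float | None = None
    encoder_provenance: str = ""
    classifier_config: dict = field(default_factory=dict)
    seed: int = 0

    def as_dict(self) -> dict:
        return {
            "probe_accuracy": self.probe_accuracy,
            "robustness_accuracy": self.robustness_accuracy,
            "supervised_accuracy": self.supervised_accuracy,
            "encoder_provenance": self.encoder_provenance,
            "classifier_config": self.classifier_config,
            "seed": self.seed,
        }


def features(net: Network, images: np.ndarray, strip_head: bool = True,
             batch_size: int = 256) -> np.ndarray:
    """Frozen-encoder features, computed in batches."""
    out = []
    for i in range(0, images.shape[0], batch_size):
        out.append(embed(net, images[i : i + batch_size], strip_head=strip_head))
    return np.concatenate(out, axis=0)


class LinearProbe:
    """Single linear layer + softmax cross-entropy, trained by Adam or SGD."""

    def __init__(self, n_features: int, n_classes: int, cfg: ProbeConfig):
        rng = np.random.default_rng(cfg.seed)
        bound = 1.0 / np.sqrt(n_features)
        self.W = rng.uniform(-bound, bound, size=(n_classes, n_features)).astype(
            np.float32
        )
        self.b = np.zeros(n_classes, dtype=np.float32)
        self.cfg = cfg
        self.opt = feedback.make_optimizer(cfg.optimizer, cfg.lr)

    def fit(self, x: np.ndarray, y: np.ndarray):
        cfg = self.cfg
        n = x.shape[0]
        if n != y.shape[0]:
            raise ValueError(f"{n} feature rows but {y.shape[0]} labels")
        rng = np.random.default_rng(cfg.seed + 1)
        x = x.astype(np.float32)
        onehot = np.eye(self.W.shape[0], dtype=np.float32)[y]
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            for i in range(0, n, cfg.batch_size):
                idx = order[i : i + cfg.batch_size]
                xb, yb = x[idx], onehot[idx]
                logits = xb @ self.W.T + self.b
                logits -= logits.max(axis=1, keepdims=True)
                p = np.exp(logits)
                p /= p.sum(axis=1, keepdims=True)
                d = (p - yb) / xb.shape[0]
                self.W = self.W + self.opt.step("W", d.T @ xb)
                self.b = self.b + self.opt.step("b", d.sum(axis=0))
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.argmax(x.astype(np.float32) @ self.W.T + self.b, axis=1)

    def accuracy(self, x: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(x) == y))


def linear_evaluation(net: Network, train_images, train_labels, test_images,
                      test_labels, cfg: ProbeConfig | None = None,
                      provenance: str = "") -> EvalReport:
    """Train a linear probe on frozen features; report held-out accuracy.

    The encoder is asserted unchanged (parameter checksums before/after).
    """
    cfg = cfg or ProbeConfig()
    before = net.checksums()
    f_train = features(net, train_images)
    f_test = features(net, test_images)
    n_classes = int(train_labels.max()) + 1
    probe = LinearProbe(f_train.shape[1], n_classes, cfg).fit(f_train, train_labels)
    acc = probe.accuracy(f_test, test_labels)
    after = net.checksums()
    if before != after:
        raise RuntimeError("encoder parameters changed during probe training")
    return EvalReport(
        probe_accuracy=acc,
        encoder_provenance=provenance,
        classifier_config=vars(cfg),
        seed=cfg.seed,
    )


def robustness_evaluation(net: Network, train_images, train_labels, test_images,
                          test_labels, deformed_test_images,
                          cfg: ProbeConfig | None = None,
                          provenance: str = "") -> EvalReport:
    """Probe trained on undeformed data, tested on a deformed test set.

    ``deformed_test_images`` must be produced by
    :func:`biossl.deformations.deform_test_set` on ``test_images`` (labels
    are preserved by deformation).
    """
    cfg = cfg or ProbeConfig()
    f_train = features(net, train_images)
    f_test = features(net, test_images)
    f_def = features(net, deformed_test_images)
    n_classes = int(train_labels.max()) + 1
    probe = LinearProbe(f_train.shape[1], n_classes, cfg).fit(f_train, train_labels)
    return EvalReport(
        probe_accuracy=probe.accuracy(f_test, test_labels),
        robustness_accuracy=probe.accuracy(f_def, test_labels),
        encoder_provenance=provenance,
        classifier_config=vars(cfg),
        seed=cfg.seed,
    )


def supervised_train(config: dict, train_images, train_labels, n_classes: int,
                     epochs: int = 10, batch_size: int = 64, lr: float = 1e-3,
                     seed: int = 0) -> Network:
    """Train the same encoder architecture end-to-end with labels (BP).

    The projection head's width is replaced by the class count and the
    network minimises softmax cross-entropy; serves as the baseline the
    robustness protocol compares against.
    """
    cfg = dict(config)
    layers = [dict(lc) for lc in cfg["layers"]]
    if layers[-1]["kind"] != "linear":
        raise ValueError("supervised baseline expects a linear top layer")
    layers[-1] = {**layers[-1], "channels": n_classes}
    layers[-1].pop("width", None)
    net = build_network({**cfg, "layers": layers}, seed=seed)
    fb = feedback.FeedbackState(rule="BP", learning_rate=lr, optimizer="adam")
    rng = np.random.default_rng(seed + 7)
    onehot = np.eye(n_classes, dtype=np.float32)[train_labels]
    n = train_images.shape[0]
    for _ in range(epochs):
        order = rng.permutation(n)
        for i in range(0, n, batch_size):
            idx = order[i : i + batch_size]
            tr = net.forward(train_images[idx])
            logits = tr.output
            logits = logits - logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            p /= p.sum(axis=1, keepdims=True)
            delta = (p - onehot[idx]) / idx.shape[0]
            deltas, _ = feedback.backward_errors(net, tr, delta, fb)
            grads = feedback.weight_gradients(net, tr, deltas)
            feedback.apply_updates(net, grads, fb)
    return net


def supervised_accuracy(net: Network, images, labels, batch_size: int = 256) -> float:
    preds = []
    for i in range(0, images.shape[0], batch_size):
        preds.append(np.argmax(net.forward(images[i : i + batch_size]).output, axis=1))
    return float(np.mean(np.concatenate(preds) == labels))


def margin_histogram(emb_A, emb_B, negatives, bins: int = 50,
                     quantiles=(0.5, 0.5)):
    """L1-distance histograms of positive and negative pairs, plus
    suggested hinge margins ``(m1, m2)`` from configurable quantiles.

    ``m1`` is the ``quantiles[0]`` quantile of positive distances, ``m2``
    the ``quantiles[1]`` quantile of negative distances; when positive
    distances stochastically dominate below negative ones and the two
    quantile levels are equal, ``m1 <= m2`` follows.
    """
    emb_A = np.asarray(emb_A, dtype=np.float64)
    emb_B = np.asarray(emb_B, dtype=np.float64)
    negatives = np.asarray(negatives)
    d_pos = np.abs(emb_A - emb_B).sum(axis=1)
    d_neg = np.abs(emb_A[:, None, :] - emb_B[negatives]).sum(axis=2).ravel()
    lo = 0.0
    hi = max(d_pos.max(), d_neg.max(), 1e-12)
    pos_hist = np.histogram(d_pos, bins=bins, range=(lo, hi))
    neg_hist = np.histogram(d_neg, bins=bins, range=(lo, hi))
    m1 = float(np.quantile(d_pos, quantiles[0]))
    m2 = float(np.quantile(d_neg, quantiles[1]))
    return {
        "pos_hist": pos_hist,
        "neg_hist": neg_hist,
        "pos_distances": d_pos,
        "neg_distances": d_neg,
        "suggested_m1": m1,
        "suggested_m2": m2,
    }
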