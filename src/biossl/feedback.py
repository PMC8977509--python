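"""Interchangeable error-propagation rules: BP, RF and URF.

Backpropagation (BP) propagates the top-layer error through the transposes
of the forward weights. Random Feedback (RF, feedback alignment) replaces
each transpose with a fixed random matrix ``B_l`` drawn at build time.
Updated Random Feedback (URF) starts from random ``B_l`` but applies to
them the *same increments* as the corresponding forward weights receive,
so that with symmetric initialisation (``B = W^T``) URF reproduces BP
exactly, step for step.

Error recursion through a hidden layer:

    delta_l = sigma'(h_l) * (M^T delta_{l+1})

with ``M = W_{l+1}`` under BP and ``M`` the feedback block under RF/URF.
Max-pool layers route error to the argmax recorded in the forward trace;
average pooling spreads it uniformly. The weight update is the Hebbian
product ``dW_l = delta_l x_{l-1}^T`` accumulated over branches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import ops
from .model_core import ConfigurationError, Network, Trace

RULES = ("BP", "RF", "URF")


class SGD:
    def __init__(self, lr: float):
        self.lr = lr

    def step(self, key, grad):
        return -self.lr * grad


class Adam:
    """Adam with the usual bias correction."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.state: dict = {}

    def step(self, key, grad):
        m, v, t = self.state.get(key, (0.0, 0.0, 0))
        t += 1
        m = self.beta1 * m + (1 - self.beta1) * grad
        v = self.beta2 * v + (1 - self.beta2) * grad * grad
        self.state[key] = (m, v, t)
        mhat = m / (1 - self.beta1**t)
        vhat = v / (1 - self.beta2**t)
        return -self.lr * mhat / (np.sqrt(vhat) + self.eps)


def make_optimizer(name: str, lr: float):
    if name == "sgd":
        return SGD(lr)
    if name == "adam":
        return Adam(lr)
    raise ConfigurationError(f"unknown optimizer {name!r}")


@dataclass
class FeedbackState:
    """Which error-propagation rule to use and how to step the weights."""

    rule: str = "BP"
    learning_rate: float = 1e-3
    optimizer: str = "sgd"
    opt: object = field(default=None, repr=False)

    def __post_init__(self):
        if self.rule not in RULES:
            raise ConfigurationError(f"rule must be one of {RULES}, got {self.rule!r}")
        if self.opt is None:
            self.opt = make_optimizer(self.optimizer, self.learning_rate)


def backward_errors(net: Network, trace: Trace, top_delta: np.ndarray,
                    fb: FeedbackState, stop: int | None = None,
                    top: int | None = None):
    """Propagate an error signal down the layers covered by ``trace``.

    ``top_delta`` is the gradient of the loss w.r.t. the output of layer
    ``top - 1`` (default: the trace's final output). Returns
    ``(deltas, delta_in)`` where ``deltas[l]`` is the error at the
    pre-activation of each trainable layer and ``delta_in`` the error
    w.r.t. the activation entering layer ``stop`` (for chaining).
    """
    stop = trace.start if stop is None else stop
    top = trace.stop if top is None else top
    if fb.rule in ("RF", "URF") and not net.feedback:
        raise ConfigurationError(f"{fb.rule} requires feedback blocks")
    delta_x = np.asarray(top_delta, dtype=net.dtype)
    deltas: dict[int, np.ndarray] = {}
    for l in reversed(range(stop, top)):
        s = net.specs[l]
        if s.activation != "none":
            delta_x = delta_x * ops.activation_grad(trace.h[l], trace.x[l], s.activation)
        if s.kind == "conv":
            deltas[l] = delta_x
            m = net.W(l) if fb.rule == "BP" else net.B(l)
            delta_x = ops.conv2d_grad_input(
                delta_x, m, trace.in_shapes[l], stride=s.stride
            )
        elif s.kind == "linear":
            deltas[l] = delta_x
            # BP: delta W; RF/URF: delta through the (in, out) feedback block
            m = net.W(l) if fb.rule == "BP" else net.B(l).T
            delta_x = delta_x @ m
        elif s.kind == "maxpool":
            delta_x = ops.maxpool_grad(
                delta_x, trace.pool_idx[l], trace.in_shapes[l], s.pool_size
            )
        elif s.kind == "avgpool":
            delta_x = ops.avgpool_grad(delta_x, trace.in_shapes[l], s.pool_size)
        elif s.kind == "flatten":
            delta_x = delta_x.reshape(trace.in_shapes[l])
    return deltas, delta_x


def weight_gradients(net: Network, trace: Trace, deltas: dict) -> dict:
    """Hebbian gradients ``dW_l = delta_l x_{l-1}^T`` (summed over batch)."""
    grads = {}
    for l, d in deltas.items():
        s = net.specs[l]
        x_prev = trace.input_to(l)
        if s.kind == "conv":
            grads[l] = ops.conv2d_grad_weight(d, x_prev, s.kernel, stride=s.stride)
        else:
            grads[l] = d.T @ x_prev
    return grads


def accumulate(total: dict, grads: dict) -> dict:
    for l, g in grads.items():
        total[l] = total.get(l, 0.0) + g
    return total


def apply_updates(net: Network, grads: dict, fb: FeedbackState) -> None:
    """Step the forward weights; under URF the feedback blocks receive the
    same increments (transposed for linear layers)."""
    for l, g in grads.items():
        if not np.all(np.isfinite(g)):
            raise ops.NumericError(f"non-finite weight update at layer {l}")
        step = fb.opt.step(("W", l), g.astype(net.dtype))
        net.params[l] = net.params[l] + step
        if fb.rule == "URF":
            if net.specs[l].kind == "linear":
                net.feedback[l] = net.feedback[l] + step.T
            else:
                net.feedback[l] = net.feedback[l] + step


def alignment_cosine(g_rule: dict, g_bp: dict) -> dict:
    """Per-layer cosine between a rule's update direction and BP's."""
    out = {}
    for l in g_rule:
        a, b = g_rule[l].ravel(), g_bp[l].ravel()
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        out[l] = float(a @ b / (na * nb)) if na > 0 and nb > 0 else 0.0
    return out
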