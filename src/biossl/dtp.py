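"""Single-step Difference Target Propagation with pooling forward stages.

The encoder is split into stages ``f_l`` — each convolution together with
its pooling layers, plus the flatten + linear projection head on top. Each
stage from the second upward owns a learned approximate inverse ``g_l``: a
strided transposed convolution whose stride undoes the stage's pooling (so
the deconvolution learns the unpooling), or a linear map for flat stages.

One training step per batch:

1. forward pass caching all stage activations ``x_l``;
2. one SGD step on every inverse, minimising the reconstruction loss
   ``L_l^inv = ||g_l(f_l(x_{l-1})) - x_{l-1}||^2`` on the clean forward
   activations;
3. targets: ``xhat_L = x_L - eta_L dL/dx_L`` at the top, then the
   difference-corrected recursion
   ``xhat_{l-1} = x_{l-1} - g_l(x_l) + g_l(xhat_l)``;
4. one SGD step on every forward stage, minimising the local loss
   ``L_l = ||f_l(x_{l-1}) - xhat_l||^2`` (the top stage descends the global
   contrastive loss directly).

The update of stage ``l`` reads only its own parameters, ``x_{l-1}`` and
``xhat_l`` — never the forward weights of the layer above, which is the
asymmetric-connection property that motivates target propagation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import feedback, losses, ops
from .model_core import ConfigurationError, Network, conv_stages


@dataclass
class DTPLosses:
    inverse: dict  # stage -> L_l^inv
    local: dict  # stage -> L_l (l < L)
    global_loss: float


class _DeconvInverse:
    """Strided transposed convolution approximating a stage's inverse."""

    def __init__(self, in_shape, out_shape, seed, dtype):
        # maps stage output (channels co, spatial so) back to stage input
        ci = out_shape[0]  # channels of the reconstruction
        co = in_shape[0]
        factor = int(round(out_shape[1] / in_shape[1]))
        self.stride = factor
        self.kernel = 4 if factor == 2 else 3
        self.pad = 1
        self.out_shape = tuple(out_shape)
        rng = np.random.default_rng([seed, 21])
        fan_in = co * self.kernel * self.kernel
        bound = 1.0 / np.sqrt(fan_in)
        self.V = rng.uniform(
            -bound, bound, size=(co, ci, self.kernel, self.kernel)
        ).astype(dtype)

    def __call__(self, z: np.ndarray) -> np.ndarray:
        n = z.shape[0]
        return ops.conv2d_grad_input(
            z, self.V, (n,) + self.out_shape, stride=self.stride, pad=self.pad
        )

    def grad(self, z: np.ndarray, dy_out: np.ndarray) -> np.ndarray:
        return ops.conv2d_grad_weight(
            z, dy_out, self.kernel, stride=self.stride, pad=self.pad
        )

    def sgd(self, g, lr):
        self.V = self.V - lr * g.astype(self.V.dtype)


class _LinearInverse:
    """Linear inverse for flat stage outputs (e.g. the projection head)."""

    def __init__(self, in_dim, out_shape, seed, dtype):
        flat = int(np.prod(out_shape))
        self.out_shape = tuple(out_shape)
        rng = np.random.default_rng([seed, 22])
        bound = 1.0 / np.sqrt(in_dim)
        self.V = rng.uniform(-bound, bound, size=(flat, in_dim)).astype(dtype)

    def __call__(self, z: np.ndarray) -> np.ndarray:
        out = z @ self.V.T
        return out.reshape((z.shape[0],) + self.out_shape)

    def grad(self, z: np.ndarray, dy_out: np.ndarray) -> np.ndarray:
        return dy_out.reshape(z.shape[0], -1).T @ z

    def sgd(self, g, lr):
        self.V = self.V - lr * g.astype(self.V.dtype)


class DTPNetwork:
    """A feed-forward network paired with learned stage inverses.

    ``inverse_lr`` is the fixed autoencoder learning rate; ``eta`` is the
    top-layer target step size (defaults to the forward learning rate).
    """

    def __init__(self, net: Network, forward_lr: float = 1e-3,
                 inverse_lr: float = 1e-3, eta: float | None = None,
                 optimizer: str = "sgd", seed: int = 0):
        self.net = net
        self.stages = conv_stages(net)
        if len(self.stages) < 2:
            raise ConfigurationError("DTP needs at least two stages")
        self.forward_lr = forward_lr
        self.inverse_lr = inverse_lr
        self.eta = forward_lr if eta is None else eta
        self.opt = feedback.make_optimizer(optimizer, forward_lr)
        self.g: dict[int, object] = {}
        for si in range(1, len(self.stages)):
            s0, s1 = self.stages[si]
            in_shape = net.input_shape if s0 == 0 else net.shapes[s0 - 1]
            out_shape = net.shapes[s1 - 1]
            if len(out_shape) == 1:
                self.g[si] = _LinearInverse(out_shape[0], in_shape, seed + si,
                                            net.dtype)
            else:
                if len(in_shape) != 3:
                    raise ConfigurationError(
                        "deconvolution inverse needs a (C,H,W) stage input"
                    )
                self.g[si] = _DeconvInverse(out_shape, in_shape, seed + si,
                                            net.dtype)

    # stage activations from a full-network trace
    def stage_outputs(self, trace):
        return {si: trace.x[s1 - 1] for si, (s0, s1) in enumerate(self.stages)}

    def stage_input(self, trace, si):
        s0, _ = self.stages[si]
        return trace.input_to(s0)


def dtp_forward(dtp: DTPNetwork, batch: np.ndarray):
    """Stage-composed forward pass; identical to the plain network forward."""
    return dtp.net.forward(batch)


def train_inverses(dtp: DTPNetwork, trace) -> dict:
    """One SGD step per inverse on its reconstruction loss (batch mean).

    Forward parameters are untouched; returns the pre-step losses.
    """
    losses_inv = {}
    n = trace.x_in.shape[0]
    for si in sorted(dtp.g, reverse=True):
        x_in = dtp.stage_input(trace, si)
        z = dtp.stage_outputs(trace)[si]
        recon = dtp.g[si](z)
        r = (recon - x_in).astype(np.float64)
        losses_inv[si] = float((r * r).sum() / n)
        gv = dtp.g[si].grad(z, (2.0 / n) * r.astype(dtp.net.dtype))
        dtp.g[si].sgd(gv, dtp.inverse_lr)
    return losses_inv


def compute_targets(dtp: DTPNetwork, trace, top_gradient: np.ndarray,
                    eta: float | None = None) -> dict:
    """Difference-corrected targets for every stage.

    ``top_gradient`` is dL/dx_L of the global loss (hinge error signals,
    with gradient blocking already honoured by the caller).
    """
    eta = dtp.eta if eta is None else eta
    outs = dtp.stage_outputs(trace)
    last = len(dtp.stages) - 1
    if top_gradient.shape != outs[last].shape:
        raise ValueError(
            f"top gradient shape {top_gradient.shape} does not match the "
            f"top activation {outs[last].shape}"
        )
    targets = {last: outs[last] - eta * top_gradient.astype(dtp.net.dtype)}
    for si in range(last, 0, -1):
        x_below = dtp.stage_input(trace, si)
        # correction computed as a difference first so the fixed point
        # (targets == activations under a zero top gradient) is exact
        targets[si - 1] = x_below + (dtp.g[si](targets[si]) - dtp.g[si](outs[si]))
    return targets


def update_forward_stages(dtp: DTPNetwork, trace, targets: dict,
                          top_gradient: np.ndarray) -> dict:
    """One step per forward stage on its local loss; returns the losses.

    Stage ``l < L`` descends ``||f_l(x_{l-1}) - xhat_l||^2 / n``; the top
    stage descends the global loss. Each stage update touches only that
    stage's parameters (locally propagated through its own pool/activation
    layers) — no transposed forward weights of any layer above are read.
    """
    net = dtp.net
    n = trace.x_in.shape[0]
    outs = dtp.stage_outputs(trace)
    last = len(dtp.stages) - 1
    local = {}
    fb_local = feedback.FeedbackState(rule="BP", learning_rate=dtp.forward_lr,
                                      optimizer="sgd", opt=dtp.opt)
    for si, (s0, s1) in enumerate(dtp.stages):
        net.access_mark(("update", si))
        if si == last:
            dy = top_gradient.astype(net.dtype)
            local[si] = None  # global loss reported separately
        else:
            diff = (outs[si] - targets[si]).astype(np.float64)
            local[si] = float((diff * diff).sum() / n)
            dy = (2.0 / n) * diff.astype(net.dtype)
        deltas, _ = feedback.backward_errors(net, trace, dy, fb_local,
                                             stop=s0, top=s1)
        grads = feedback.weight_gradients(net, trace, deltas)
        for l, g in grads.items():
            step = dtp.opt.step(("W", l), g.astype(net.dtype))
            net.params[l] = net.params[l] + step
    net.access_mark(None)
    return local


def dtp_step(dtp: DTPNetwork, views, loss_cfg: losses.HingeLossConfig) -> DTPLosses:
    """One full DTP step on a pair of view batches.

    The anchor branch is forwarded only to form the error signals; with
    gradient blocking (the default) the inverse training, targets and
    forward updates all run on the B-branch trace. Without blocking the
    anchor trace receives its own target pass and updates as well.
    """
    net = dtp.net
    tr_b = net.forward(views.view_B)
    tr_a = net.forward(views.view_A)
    emb_a, emb_b = tr_a.output, tr_b.output
    negs = views.negatives
    gloss, _ = losses.hinge_loss(emb_a, emb_b, negs, loss_cfg)
    err = losses.hinge_error_signals(emb_a, emb_b, negs, loss_cfg)
    g_a, g_b = losses.embedding_gradients(err, negs, loss_cfg.block_gradient)

    inv = train_inverses(dtp, tr_b)
    targets = compute_targets(dtp, tr_b, g_b.astype(net.dtype))
    local = update_forward_stages(dtp, tr_b, targets, g_b.astype(net.dtype))
    if not loss_cfg.block_gradient:
        targets_a = compute_targets(dtp, tr_a, g_a.astype(net.dtype))
        update_forward_stages(dtp, tr_a, targets_a, g_a.astype(net.dtype))
    return DTPLosses(inverse=inv, local=local, global_loss=gloss)


def train_dtp(dtp: DTPNetwork, stream, steps: int,
              loss_cfg: losses.HingeLossConfig, log=None):
    history = []
    for step in range(steps):
        views = next(stream)
        out = dtp_step(dtp, views, loss_cfg)
        history.append(out.global_loss)
        if log is not None:
            log.writerow([step, "dtp", f"{out.global_loss:.6f}"])
    return history
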