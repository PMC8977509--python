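"""End-to-end SSL training with the contrastive hinge loss.

One step: forward both deformed view batches, evaluate the hinge loss,
form the closed-form top-layer error signals, propagate them down with the
configured rule (BP / RF / URF) and apply Hebbian updates accumulated over
the contributing branches. With gradient blocking (the default) the anchor
branch contributes no gradient, so only the B-branch forward pass needs a
backward sweep.
"""

from __future__ import annotations

from . import feedback, losses
from .deformations import ViewBatch
from .model_core import Network


def hinge_ssl_step(net: Network, views: ViewBatch, loss_cfg: losses.HingeLossConfig,
                   fb: feedback.FeedbackState) -> float:
    """One training step; returns the (pre-update) batch loss."""
    tr_a = net.forward(views.view_A)
    tr_b = net.forward(views.view_B)
    emb_a, emb_b = tr_a.output, tr_b.output
    negs = views.negatives
    loss, _ = losses.hinge_loss(emb_a, emb_b, negs, loss_cfg)
    err = losses.hinge_error_signals(emb_a, emb_b, negs, loss_cfg)
    g_a, g_b = losses.embedding_gradients(err, negs, loss_cfg.block_gradient)
    grads: dict = {}
    if not loss_cfg.block_gradient:
        deltas_a, _ = feedback.backward_errors(net, tr_a, g_a, fb)
        feedback.accumulate(grads, feedback.weight_gradients(net, tr_a, deltas_a))
    deltas_b, _ = feedback.backward_errors(net, tr_b, g_b, fb)
    feedback.accumulate(grads, feedback.weight_gradients(net, tr_b, deltas_b))
    feedback.apply_updates(net, grads, fb)
    return loss


def train_e2e(net: Network, stream, steps: int, loss_cfg: losses.HingeLossConfig,
              fb: feedback.FeedbackState, log=None) -> list:
    """Run ``steps`` batches from a :func:`~biossl.deformations.view_stream`."""
    history = []
    for step in range(steps):
        views = next(stream)
        loss = hinge_ssl_step(net, views, loss_cfg, fb)
        history.append(loss)
        if log is not None:
            log.writerow([step, "e2e", f"{loss:.6f}"])
    return history


def batch_hinge_loss(net: Network, views: ViewBatch,
                     loss_cfg: losses.HingeLossConfig) -> float:
    """Evaluate the hinge loss on a fixed view batch without updating."""
    emb_a = net.forward(views.view_A).output
    emb_b = net.forward(views.view_B).output
    loss, _ = losses.hinge_loss(emb_a, emb_b, views.negatives, loss_cfg)
    return loss
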