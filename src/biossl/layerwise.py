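"""Greedy and randomized layer-wise learning with auxiliary heads.

The encoder is split into stages (each convolution with its adjacent
pooling layers). Every stage owns an auxiliary projection head — flatten
followed by a linear map into the embedding space — so that the
contrastive hinge loss can be computed directly above the stage being
trained. At any step exactly one stage and its head are updated: the
network below provides frozen inputs, nothing above is consulted, and the
single-hidden-layer error propagation uses BP, RF or URF.

GLL trains the stages strictly bottom-to-top, each to a budget of steps.
RLL draws the trained stage uniformly at random for every batch, so all
stages learn simultaneously without any sequencing of updates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import feedback, losses
from .model_core import ConfigurationError, Network, conv_stages


@dataclass
class LayerwiseSchedule:
    mode: str = "GLL"  # GLL | RLL
    steps_per_layer: int = 200  # GLL budget per stage
    total_steps: int = 1000  # RLL budget
    seed: int = 0  # RLL layer-sampling seed

    def __post_init__(self):
        if self.mode not in ("GLL", "RLL"):
            raise ConfigurationError("mode must be GLL or RLL")


class AuxiliaryHead:
    """Flatten + linear map from a stage's output to the embedding space."""

    def __init__(self, in_shape, embed_dim: int, seed: int, dtype=np.float32):
        self.in_shape = tuple(in_shape)
        flat = int(np.prod(in_shape))
        rng_w = np.random.default_rng([seed, 11])
        rng_b = np.random.default_rng([seed, 12])
        bound = 1.0 / np.sqrt(flat)
        self.W = rng_w.uniform(-bound, bound, size=(embed_dim, flat)).astype(dtype)
        self.B = rng_b.uniform(-bound, bound, size=(flat, embed_dim)).astype(dtype)

    def forward(self, x: np.ndarray):
        flat = x.reshape(x.shape[0], -1)
        return flat, flat @ self.W.T


def _stage_step(net: Network, stage, head: AuxiliaryHead, x_in_a, x_in_b,
                negatives, loss_cfg, fb: feedback.FeedbackState,
                head_key) -> float:
    """Train one stage + its head on a pair of stage-input batches.

    ``x_in_a`` / ``x_in_b`` are the activations entering the stage for the
    two branches (already forwarded through the frozen layers below).
    """
    s0, s1 = stage
    tr_a = net.forward(x_in_a, start=s0, stop=s1)
    tr_b = net.forward(x_in_b, start=s0, stop=s1)
    flat_a, emb_a = head.forward(tr_a.output)
    flat_b, emb_b = head.forward(tr_b.output)
    loss, _ = losses.hinge_loss(emb_a, emb_b, negatives, loss_cfg)
    err = losses.hinge_error_signals(emb_a, emb_b, negatives, loss_cfg)
    g_a, g_b = losses.embedding_gradients(err, negatives, loss_cfg.block_gradient)

    grads: dict = {}
    g_head = np.zeros_like(head.W, dtype=np.float64)
    branches = [(g_b, tr_b, flat_b)]
    if not loss_cfg.block_gradient:
        branches.insert(0, (g_a, tr_a, flat_a))
    for g_emb, tr, flat in branches:
        g_emb = g_emb.astype(net.dtype)
        g_head += g_emb.T @ flat
        # single-hidden-layer error propagation to the stage output
        m = head.W if fb.rule == "BP" else head.B.T
        d_flat = g_emb @ m
        d_stage = d_flat.reshape(tr.output.shape)
        deltas, _ = feedback.backward_errors(net, tr, d_stage, fb, stop=s0)
        feedback.accumulate(grads, feedback.weight_gradients(net, tr, deltas))

    feedback.apply_updates(net, grads, fb)
    step = fb.opt.step(head_key, g_head.astype(net.dtype))
    head.W = head.W + step
    if fb.rule == "URF":
        head.B = head.B + step.T
    return loss


def make_heads(net: Network, stages, embed_dim: int, seed: int) -> dict:
    heads = {}
    for si, (s0, s1) in enumerate(stages):
        heads[si] = AuxiliaryHead(net.shapes[s1 - 1], embed_dim, seed + si, net.dtype)
    return heads


def calibrate_stage_margins(net: Network, heads: dict, stages, views,
                            base_cfg: losses.HingeLossConfig,
                            quantiles=(0.1, 0.9)) -> dict:
    """Per-stage hinge margins from each auxiliary head's initial
    positive/negative distance histograms.

    Each stage optimises the contrastive loss in its own embedding space,
    whose distance scale depends on the head and on feature statistics at
    that depth; bracketing margins are therefore derived per stage (m1 at
    ``quantiles[0]`` of the positive distances, m2 at ``quantiles[1]`` of
    the negative distances), mirroring the histogram-based margin choice.
    """
    from .evaluation import margin_histogram

    tr_a = net.forward(views.view_A)
    tr_b = net.forward(views.view_B)
    cfgs = {}
    for si, (s0, s1) in enumerate(stages):
        _, emb_a = heads[si].forward(tr_a.x[s1 - 1])
        _, emb_b = heads[si].forward(tr_b.x[s1 - 1])
        h = margin_histogram(emb_a, emb_b, views.negatives, quantiles=quantiles)
        cfgs[si] = losses.HingeLossConfig(
            m1=max(h["suggested_m1"], 1e-6), m2=max(h["suggested_m2"], 1e-6),
            T=base_cfg.T, block_gradient=base_cfg.block_gradient,
        )
    return cfgs


def _trainable_stages(net: Network):
    """Conv stages only — the projection head is replaced by aux heads."""
    return [st for st in conv_stages(net) if net.specs[st[0]].kind == "conv"]


def gll_train(net: Network, stream, schedule: LayerwiseSchedule,
              loss_cfg: losses.HingeLossConfig, fb_template: feedback.FeedbackState,
              embed_dim: int = 64, log=None, stage_loss_cfgs: dict | None = None):
    """Greedy layer-wise training, stages trained bottom-to-top.

    ``stage_loss_cfgs`` optionally maps stage index to a per-stage hinge
    configuration (see :func:`calibrate_stage_margins`); stages fall back
    to ``loss_cfg``. Returns ``(net, history)`` where ``history[si]`` is
    the per-step loss trace of stage ``si``. Head parameters of finished
    stages are discarded (evaluation attaches its own linear classifier).
    """
    stages = _trainable_stages(net)
    heads = make_heads(net, stages, embed_dim, schedule.seed)
    stage_loss_cfgs = stage_loss_cfgs or {}
    history = {}
    for si, stage in enumerate(stages):
        cfg_si = stage_loss_cfgs.get(si, loss_cfg)
        fb = feedback.FeedbackState(
            rule=fb_template.rule,
            learning_rate=fb_template.learning_rate,
            optimizer=fb_template.optimizer,
        )
        trace = []
        for step in range(schedule.steps_per_layer):
            views = next(stream)
            x_a = net.forward(views.view_A, stop=stage[0]).output
            x_b = net.forward(views.view_B, stop=stage[0]).output
            loss = _stage_step(
                net, stage, heads[si], x_a, x_b, views.negatives, cfg_si, fb,
                head_key=("head", si),
            )
            trace.append(loss)
            if log is not None:
                log.writerow([step, f"gll_stage{si}", f"{loss:.6f}"])
        history[si] = trace
    return net, history


def rll_train(net: Network, stream, schedule: LayerwiseSchedule,
              loss_cfg: losses.HingeLossConfig, fb_template: feedback.FeedbackState,
              embed_dim: int = 64, log=None, stage_loss_cfgs: dict | None = None):
    """Randomized layer-wise training: one uniformly drawn stage per batch.

    Data is forwarded through the preceding stages at their current values;
    only the drawn stage and its head are updated. Returns
    ``(net, history)`` with ``history`` a list of ``(stage, loss)`` pairs.
    """
    stages = _trainable_stages(net)
    heads = make_heads(net, stages, embed_dim, schedule.seed)
    stage_loss_cfgs = stage_loss_cfgs or {}
    fbs = {
        si: feedback.FeedbackState(
            rule=fb_template.rule,
            learning_rate=fb_template.learning_rate,
            optimizer=fb_template.optimizer,
        )
        for si in range(len(stages))
    }
    rng = np.random.default_rng(schedule.seed)
    history = []
    for step in range(schedule.total_steps):
        si = int(rng.integers(0, len(stages)))
        stage = stages[si]
        views = next(stream)
        x_a = net.forward(views.view_A, stop=stage[0]).output
        x_b = net.forward(views.view_B, stop=stage[0]).output
        loss = _stage_step(
            net, stage, heads[si], x_a, x_b, views.negatives,
            stage_loss_cfgs.get(si, loss_cfg), fbs[si],
            head_key=("head", si),
        )
        history.append((si, loss))
        if log is not None:
            log.writerow([step, f"rll_stage{si}", f"{loss:.6f}"])
    return net, history
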