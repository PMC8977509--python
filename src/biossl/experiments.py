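"""Desk-scale experiment protocols on the synthetic fixture.

These functions wire the whole pipeline together at sizes that run in
minutes on one CPU: every trainer (end-to-end, greedy layer-wise,
randomized layer-wise, difference target propagation) crossed with every
update rule (BP, RF, URF) on the default synthetic shape dataset, plus the
linear-probe and deformation-robustness protocols. They are the package's
reference experiments; the command line and the reproduction script both
call into them.

Problem sizes (chosen once for the desk-scale regime): a 3-stage encoder
(16/32/64 channels, max-pool 2 after each convolution, tanh) with a
64-dimensional projection head on 28x28 single-channel images; batches of
32 positive pairs; hinge margins m1 = 1, m2 = 1.5 with T = 5 negatives and
gradient blocking; Adam at learning rate 1e-3.
"""

from __future__ import annotations

import numpy as np

from . import dtp as dtpmod
from . import evaluation, feedback, layerwise, losses, synthetic, training
from .deformations import DeformationConfig, deform_test_set, view_stream
from .model_core import build_network

DESK_NETWORK = {
    "input_shape": [1, 28, 28],
    "layers": [
        {"kind": "conv", "channels": 16, "kernel": 3, "stride": 1},
        {"kind": "maxpool", "size": 2, "activation": "tanh"},
        {"kind": "conv", "channels": 32, "kernel": 3, "stride": 1},
        {"kind": "maxpool", "size": 2, "activation": "tanh"},
        {"kind": "conv", "channels": 64, "kernel": 3, "stride": 1},
        {"kind": "maxpool", "size": 2, "activation": "tanh"},
        {"kind": "flatten"},
        {"kind": "linear", "width": 64},
    ],
}

DESK_LOSS = dict(m1=1.0, m2=1.5, T=5, block_gradient=True)
DESK_BATCH = 32
DESK_LR = 1e-3
# random feedback needs conservative step sizes: misaligned updates
# amplify at larger rates (most severely when propagated through depth)
DESK_LR_E2E_RF = 3e-4
DESK_LR_LAYERWISE_RF = 5e-4
# faster autoencoder learning gives more faithful inverses, hence better
# targets, within the short desk-scale budget
DESK_DTP_INVERSE_LR = 3e-3
# margin calibration quantiles: m1 brackets the positive distances from
# below, m2 the negative distances from above, so initially most pairs are
# active (the histogram-based margin choice)
MARGIN_QUANTILES = (0.1, 0.9)


def desk_deformations(seed: int) -> DeformationConfig:
    """Single-channel 28-px view deformations: crop/shift + brightness/contrast."""
    return DeformationConfig(
        crop_size=28,
        crop_scale_range=(0.5, 1.0),
        flip_prob=0.5,
        jitter_strengths=(0.4, 0.4, 0.0, 0.0),
        grayscale_prob=0.0,
        seed=seed,
    )


def desk_dataset(seed: int) -> synthetic.Dataset:
    return synthetic.generate(synthetic.SyntheticDatasetSpec(seed=seed))


def _eval_views(images: np.ndarray, seed: int, n: int = 64):
    """A fixed view batch for before/after loss comparisons."""
    rng = np.random.default_rng(seed)
    idx = rng.choice(images.shape[0], size=n, replace=False)
    cfg = desk_deformations(seed + 1)
    from .deformations import make_views

    return make_views(images[idx], cfg, n_negatives=DESK_LOSS["T"])


def calibrated_loss_cfg(net, eval_views) -> losses.HingeLossConfig:
    """Hinge margins derived from the initial distance distributions.

    Following the histogram-based margin choice, ``m1`` is set below the
    bulk of the initial positive distances and ``m2`` above the bulk of the
    initial negative distances, so that optimisation starts with most
    pairs active and converges onto the problematic ones.
    """
    from . import evaluation

    emb_a = net.forward(eval_views.view_A).output
    emb_b = net.forward(eval_views.view_B).output
    h = evaluation.margin_histogram(emb_a, emb_b, eval_views.negatives,
                                    quantiles=MARGIN_QUANTILES)
    return losses.HingeLossConfig(
        m1=h["suggested_m1"], m2=h["suggested_m2"], T=DESK_LOSS["T"],
        block_gradient=DESK_LOSS["block_gradient"],
    )


def train_combo(images: np.ndarray, trainer: str, rule: str, seed: int,
                steps: int = 200):
    """Train one trainer x rule combination for ``steps`` batches.

    Returns ``(initial_loss, final_loss, trained_object)`` where both
    losses are evaluated on the same held-out view batch through the
    parameters the trainer actually optimises (the projection head for
    end-to-end and DTP; the top auxiliary head for the layer-wise modes).
    """
    net = build_network(DESK_NETWORK, seed=seed)
    loss_cfg = calibrated_loss_cfg(net, _eval_views(images, seed + 4))
    stream = view_stream(images, DESK_BATCH, desk_deformations(seed + 2),
                         loss_cfg.T, seed + 3)
    eval_views = _eval_views(images, seed + 4)

    if trainer in ("gll", "rll"):
        stages = layerwise._trainable_stages(net)
        heads = layerwise.make_heads(net, stages, 64, seed + 5)
        top = len(stages) - 1
        stage_cfgs = layerwise.calibrate_stage_margins(
            net, heads, stages, _eval_views(images, seed + 4), loss_cfg,
            quantiles=MARGIN_QUANTILES,
        )

        def head_loss():
            tr_a = net.forward(eval_views.view_A)
            tr_b = net.forward(eval_views.view_B)
            s1 = stages[top][1]
            _, ea = heads[top].forward(tr_a.x[s1 - 1])
            _, eb = heads[top].forward(tr_b.x[s1 - 1])
            return losses.hinge_loss(ea, eb, eval_views.negatives,
                                     stage_cfgs[top])[0]

        init_loss = head_loss()
        lr = DESK_LR_LAYERWISE_RF if rule.upper() == "RF" else DESK_LR
        fb = feedback.FeedbackState(rule=rule.upper(), learning_rate=lr,
                                    optimizer="adam")
        if trainer == "gll":
            sched = layerwise.LayerwiseSchedule(
                mode="GLL", steps_per_layer=max(1, steps // len(stages)),
                seed=seed + 5,
            )
            _run_layerwise_with_heads(net, heads, stages, stream, sched,
                                      stage_cfgs, fb)
        else:
            sched = layerwise.LayerwiseSchedule(mode="RLL", total_steps=steps,
                                                seed=seed + 5)
            _run_rll_with_heads(net, heads, stages, stream, sched, stage_cfgs, fb)
        return init_loss, head_loss(), net

    if trainer == "e2e":
        init_loss = training.batch_hinge_loss(net, eval_views, loss_cfg)
        lr = DESK_LR_E2E_RF if rule.upper() == "RF" else DESK_LR
        fb = feedback.FeedbackState(rule=rule.upper(), learning_rate=lr,
                                    optimizer="adam")
        training.train_e2e(net, stream, steps, loss_cfg, fb)
        return init_loss, training.batch_hinge_loss(net, eval_views, loss_cfg), net

    if trainer == "dtp":
        init_loss = training.batch_hinge_loss(net, eval_views, loss_cfg)
        d = dtpmod.DTPNetwork(net, forward_lr=DESK_LR,
                              inverse_lr=DESK_DTP_INVERSE_LR,
                              optimizer="adam", seed=seed + 6)
        dtpmod.train_dtp(d, stream, steps, loss_cfg)
        return init_loss, training.batch_hinge_loss(net, eval_views, loss_cfg), d

    raise ValueError(f"unknown trainer {trainer!r}")


def _run_layerwise_with_heads(net, heads, stages, stream, sched, stage_cfgs, fb_t):
    for si, stage in enumerate(stages):
        fb = feedback.FeedbackState(rule=fb_t.rule, learning_rate=fb_t.learning_rate,
                                    optimizer=fb_t.optimizer)
        for _ in range(sched.steps_per_layer):
            views = next(stream)
            x_a = net.forward(views.view_A, stop=stage[0]).output
            x_b = net.forward(views.view_B, stop=stage[0]).output
            layerwise._stage_step(net, stage, heads[si], x_a, x_b,
                                  views.negatives, stage_cfgs[si], fb,
                                  ("head", si))


def _run_rll_with_heads(net, heads, stages, stream, sched, stage_cfgs, fb_t):
    fbs = {
        si: feedback.FeedbackState(rule=fb_t.rule, learning_rate=fb_t.learning_rate,
                                   optimizer=fb_t.optimizer)
        for si in range(len(stages))
    }
    rng = np.random.default_rng(sched.seed)
    for _ in range(sched.total_steps):
        si = int(rng.integers(0, len(stages)))
        stage = stages[si]
        views = next(stream)
        x_a = net.forward(views.view_A, stop=stage[0]).output
        x_b = net.forward(views.view_B, stop=stage[0]).output
        layerwise._stage_step(net, stage, heads[si], x_a, x_b, views.negatives,
                              stage_cfgs[si], fbs[si], ("head", si))


ALL_COMBOS = [
    ("e2e", "BP"), ("e2e", "RF"), ("e2e", "URF"),
    ("gll", "BP"), ("gll", "RF"), ("gll", "URF"),
    ("rll", "BP"), ("rll", "RF"), ("rll", "URF"),
    ("dtp", "-"),
]


def loss_reduction_sweep(seed: int, steps: int = 200) -> dict:
    """Fractional hinge-loss reduction for every trainer x rule combination."""
    ds = desk_dataset(seed)
    images = ds.train[0]
    out = {}
    for trainer, rule in ALL_COMBOS:
        init_l, final_l, _ = train_combo(images, trainer, rule, seed, steps=steps)
        out[f"{trainer}_{rule.lower()}" if rule != "-" else "dtp"] = {
            "initial": init_l,
            "final": final_l,
            "reduction": 1.0 - final_l / init_l if init_l > 0 else 1.0,
        }
    return out


def representation_experiment(seed: int, ssl_steps: int = 400,
                              probe_epochs: int = 30,
                              supervised_epochs: int = 30,
                              labeled_per_class: int = 25) -> dict:
    """Probe and robustness accuracies for one seed.

    The encoder is pretrained on the full unlabeled training split; the
    downstream classifiers — the linear probes and the supervised baseline
    alike — see only a small labeled subset (``labeled_per_class``
    images per class), mirroring the regime where robust embeddings matter
    most: plenty of unlabeled experience, scarce labels. All comparisons
    that involve deformations use an affine-deformed copy of the test set,
    a deformation family the classifiers never saw.
    """
    ds = desk_dataset(seed)
    train_x, train_y = ds.train
    test_x, test_y = ds.test
    # stratified labeled subset for the classifiers
    rng = np.random.default_rng(seed + 13)
    lab_idx = np.concatenate(
        [
            rng.choice(np.flatnonzero(train_y == c), labeled_per_class,
                       replace=False)
            for c in range(int(train_y.max()) + 1)
        ]
    )
    lab_x, lab_y = train_x[lab_idx], train_y[lab_idx]

    # SSL pretraining (end-to-end, blocked gradients, Adam)
    net = build_network(DESK_NETWORK, seed=seed)
    random_net = net.copy()
    loss_cfg = calibrated_loss_cfg(net, _eval_views(train_x, seed + 4))
    stream = view_stream(train_x, DESK_BATCH, desk_deformations(seed + 2),
                         loss_cfg.T, seed + 3)
    fb = feedback.FeedbackState(rule="BP", learning_rate=DESK_LR, optimizer="adam")
    training.train_e2e(net, stream, ssl_steps, loss_cfg, fb)

    probe_cfg = evaluation.ProbeConfig(epochs=probe_epochs, seed=seed)
    # deformed test set from the crop/jitter family: seen by the encoder
    # during unlabeled pretraining, never by any classifier's labeled data
    deformed = deform_test_set(test_x, desk_deformations(seed + 9))

    rep_trained = evaluation.robustness_evaluation(
        net, lab_x, lab_y, test_x, test_y, deformed, probe_cfg,
        provenance="ssl-e2e-bp",
    )
    rep_random = evaluation.robustness_evaluation(
        random_net, lab_x, lab_y, test_x, test_y, deformed, probe_cfg,
        provenance="random-encoder",
    )

    sup = evaluation.supervised_train(
        DESK_NETWORK, lab_x, lab_y, n_classes=int(train_y.max()) + 1,
        epochs=supervised_epochs, batch_size=64, lr=DESK_LR, seed=seed,
    )
    sup_def = evaluation.supervised_accuracy(sup, deformed, test_y)
    sup_plain = evaluation.supervised_accuracy(sup, test_x, test_y)
    return {
        "trained_probe": rep_trained.probe_accuracy,
        "random_probe": rep_random.probe_accuracy,
        "trained_probe_deformed": rep_trained.robustness_accuracy,
        "random_probe_deformed": rep_random.robustness_accuracy,
        "ssl_deformed": rep_trained.robustness_accuracy,
        "supervised_deformed": sup_def,
        "supervised_plain": sup_plain,
    }
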