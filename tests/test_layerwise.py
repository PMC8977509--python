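"""Greedy and randomized layer-wise training: isolation contracts,
uniform layer sampling, and per-stage convergence."""

import numpy as np
import pytest
from scipy import stats

from biossl import experiments, feedback, layerwise, losses
from biossl.deformations import view_stream
from biossl.model_core import build_network
from biossl.presets import network_config


def small_setup(seed=1, images_per_class=30):
    from biossl.synthetic import SyntheticDatasetSpec, generate

    ds = generate(SyntheticDatasetSpec(images_per_class=images_per_class,
                                       seed=seed))
    net = build_network(network_config("synth_small"), seed=seed)
    # margins bracketing the initial distance distributions (the same
    # histogram-based calibration the reference experiments use)
    loss_cfg = experiments.calibrated_loss_cfg(
        net, experiments._eval_views(ds.train[0], seed)
    )
    stream = view_stream(ds.train[0], 16, experiments.desk_deformations(seed + 1),
                         5, seed + 2)
    return net, loss_cfg, stream


def test_gll_freezes_all_other_blocks():
    """After each stage, parameter blocks of other stages are bit-identical
    to their pre-stage values."""
    net, loss_cfg, stream = small_setup()
    stages = layerwise._trainable_stages(net)
    heads = layerwise.make_heads(net, stages, 64, 9)
    fb_t = feedback.FeedbackState(rule="BP", learning_rate=1e-3, optimizer="adam")
    for si, stage in enumerate(stages):
        before = {l: net.params[l].copy() for l in net.trainable_layers}
        fb = feedback.FeedbackState(rule="BP", learning_rate=1e-3, optimizer="adam")
        for _ in range(3):
            views = next(stream)
            x_a = net.forward(views.view_A, stop=stage[0]).output
            x_b = net.forward(views.view_B, stop=stage[0]).output
            layerwise._stage_step(net, stage, heads[si], x_a, x_b,
                                  views.negatives, loss_cfg, fb, ("head", si))
        stage_layers = set(range(*stage))
        for l in net.trainable_layers:
            if l in stage_layers:
                assert not np.array_equal(before[l], net.params[l])
            else:
                assert np.array_equal(before[l], net.params[l])


def test_rll_step_touches_exactly_selected_stage_and_head():
    net, loss_cfg, stream = small_setup(seed=2)
    stages = layerwise._trainable_stages(net)
    heads = layerwise.make_heads(net, stages, 64, 3)
    si = 1
    stage = stages[si]
    before_w = {l: net.params[l].copy() for l in net.trainable_layers}
    before_heads = {k: h.W.copy() for k, h in heads.items()}
    fb = feedback.FeedbackState(rule="BP", learning_rate=1e-3, optimizer="adam")
    views = next(stream)
    x_a = net.forward(views.view_A, stop=stage[0]).output
    x_b = net.forward(views.view_B, stop=stage[0]).output
    layerwise._stage_step(net, stage, heads[si], x_a, x_b, views.negatives,
                          loss_cfg, fb, ("head", si))
    changed = [l for l in net.trainable_layers
               if not np.array_equal(before_w[l], net.params[l])]
    assert changed == [stage[0]]  # exactly the selected conv block
    heads_changed = [k for k in heads
                     if not np.array_equal(before_heads[k], heads[k].W)]
    assert heads_changed == [si]


def test_stage_update_never_reads_layers_above():
    """Locking freedom: the single-hidden-layer update consults nothing
    above the trained stage except its own head."""
    net, loss_cfg, stream = small_setup(seed=3)
    stages = layerwise._trainable_stages(net)
    heads = layerwise.make_heads(net, stages, 64, 4)
    si, stage = 0, stages[0]
    views = next(stream)
    x_a = views.view_A
    x_b = views.view_B
    fb = feedback.FeedbackState(rule="RF", learning_rate=1e-3, optimizer="adam")
    with net.trace_access() as log:
        net.access_mark(("stage", si))
        layerwise._stage_step(net, stage, heads[si], x_a, x_b, views.negatives,
                              loss_cfg, fb, ("head", si))
    assert log
    for _, layer, _block in log:
        assert layer in range(*stage)


def test_rll_layer_draws_uniform():
    """Chi-square goodness of fit of the stage-selection frequencies."""
    rng = np.random.default_rng(7)
    k, n = 3, 10_000
    draws = rng.integers(0, k, size=n)  # the same sampling RLL uses
    counts = np.bincount(draws, minlength=k)
    chi2, p = stats.chisquare(counts)
    assert p > 0.001


def test_rll_selection_matches_schedule_seed():
    net, loss_cfg, stream = small_setup(seed=4)
    sched = layerwise.LayerwiseSchedule(mode="RLL", total_steps=20, seed=11)
    fb = feedback.FeedbackState(rule="BP", learning_rate=1e-3, optimizer="adam")
    _, hist = layerwise.rll_train(net, stream, sched, loss_cfg, fb)
    expected = [int(s) for s in np.random.default_rng(11).integers(0, 3, size=20)]
    assert [si for si, _ in hist] == expected


def test_gll_per_stage_loss_decreases():
    """Within each stage the training loss falls from start to finish
    (each stage's margins bracket its own initial distance histogram)."""
    net, loss_cfg, stream = small_setup(seed=5, images_per_class=60)
    sched = layerwise.LayerwiseSchedule(mode="GLL", steps_per_layer=40, seed=5)
    stages = layerwise._trainable_stages(net)
    heads = layerwise.make_heads(net, stages, 64, sched.seed)
    views = next(stream)
    stage_cfgs = layerwise.calibrate_stage_margins(net, heads, stages, views,
                                                   loss_cfg)
    # conservative rate: each stage descends monotonically instead of
    # overshooting through the early expansion transient
    fb = feedback.FeedbackState(rule="BP", learning_rate=1e-4, optimizer="adam")
    _, hist = layerwise.gll_train(net, stream, sched, loss_cfg, fb,
                                  stage_loss_cfgs=stage_cfgs)
    for si, trace in hist.items():
        assert np.mean(trace[-5:]) < np.mean(trace[:5])


def test_one_layer_gll_equals_end_to_end_bp():
    """Degenerate case: a single-stage network trained layer-wise with BP
    takes the same steps as end-to-end BP with the same head."""
    from biossl import training
    from biossl.deformations import ViewBatch, negative_sets
    from biossl.model_core import LayerSpec, Network

    n, T = 4, 2
    negs = negative_sets(n, T)
    loss_cfg = losses.HingeLossConfig(m1=0.2, m2=1.0, T=T)

    specs_full = [
        LayerSpec("conv", activation="tanh", channels_out=3, kernel=3),
        LayerSpec("flatten"),
        LayerSpec("linear", channels_out=4),
    ]
    e2e_net = Network(specs_full, (1, 5, 5), seed=6, dtype=np.float64)
    lw_net = Network(specs_full, (1, 5, 5), seed=6, dtype=np.float64)
    stages = layerwise._trainable_stages(lw_net)
    assert len(stages) == 1
    head = layerwise.AuxiliaryHead(lw_net.shapes[0], 4, seed=0, dtype=np.float64)
    head.W = e2e_net.params[2].copy()  # same projection as the e2e head
    fb_e = feedback.FeedbackState(rule="BP", learning_rate=0.01)
    fb_l = feedback.FeedbackState(rule="BP", learning_rate=0.01)
    rng = np.random.default_rng(12)
    for _ in range(10):
        a = rng.uniform(size=(n, 1, 5, 5))
        b = rng.uniform(size=(n, 1, 5, 5))
        training.hinge_ssl_step(e2e_net, ViewBatch(a, b, negs), loss_cfg, fb_e)
        layerwise._stage_step(lw_net, stages[0], head, a, b, negs, loss_cfg,
                              fb_l, ("head", 0))
    assert np.allclose(e2e_net.params[0], lw_net.params[0], atol=1e-12)
    assert np.allclose(e2e_net.params[2], head.W, atol=1e-12)


@pytest.mark.parametrize("mode", ["GLL", "RLL"])
@pytest.mark.parametrize("rule", ["BP", "RF", "URF"])
def test_every_mode_rule_combination_reduces_loss(mode, rule, tiny_dataset):
    images = tiny_dataset.train[0]
    trainer = mode.lower()
    init_l, final_l, _ = experiments.train_combo(images, trainer, rule, seed=1,
                                                 steps=90)
    assert final_l < init_l
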