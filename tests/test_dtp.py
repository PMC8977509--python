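"""Difference target propagation: fixed points, inverse training, the
hand-unrolled single-step algorithm, and the asymmetric-connection
contract."""

import numpy as np
import pytest

from biossl import dtp as dtpmod
from biossl import losses
from biossl.model_core import LayerSpec, Network
from conftest import finite_difference


def two_stage_linear(seed=0):
    """Two linear stages: tanh hidden stage + linear top stage."""
    specs = [
        LayerSpec("linear", activation="tanh", channels_out=3),
        LayerSpec("linear", channels_out=2),
    ]
    return Network(specs, (4,), seed=seed, dtype=np.float64)


def test_dtp_forward_equals_plain_forward(toy_net, rng):
    d = dtpmod.DTPNetwork(toy_net, seed=1)
    x = rng.uniform(size=(3, 2, 8, 8))
    tr1 = dtpmod.dtp_forward(d, x)
    tr2 = toy_net.forward(x)
    assert np.array_equal(tr1.output, tr2.output)
    outs = d.stage_outputs(tr1)
    for si, (s0, s1) in enumerate(d.stages):
        assert np.array_equal(outs[si], tr2.x[s1 - 1])


def test_zero_input_zero_stages_zero_trace(toy_net):
    d = dtpmod.DTPNetwork(toy_net, seed=1)
    tr = dtpmod.dtp_forward(d, np.zeros((2, 2, 8, 8)))
    assert np.all(tr.output == 0)


def test_zero_top_gradient_fixed_point_is_exact(toy_net, rng):
    """Targets equal activations and local losses are exactly zero."""
    d = dtpmod.DTPNetwork(toy_net, forward_lr=0.05, seed=2)
    tr = toy_net.forward(rng.uniform(size=(4, 2, 8, 8)))
    zero = np.zeros_like(tr.output)
    targets = dtpmod.compute_targets(d, tr, zero)
    outs = d.stage_outputs(tr)
    for si in targets:
        assert np.array_equal(targets[si], outs[si])
    before = toy_net.checksums()
    local = dtpmod.update_forward_stages(d, tr, targets, zero)
    for si, v in local.items():
        if v is not None:
            assert v == 0.0
    after = toy_net.checksums()
    assert before == after  # zero gradients leave every block untouched


def test_exact_inverse_gives_direct_target_propagation(rng):
    """When g_l inverts f_l exactly, the difference correction cancels and
    xhat_{l-1} = g_l(xhat_l)."""
    net = two_stage_linear(seed=3)
    d = dtpmod.DTPNetwork(net, seed=3)
    # make the top stage invertible by construction: W square orthogonal
    q, _ = np.linalg.qr(np.random.default_rng(0).normal(size=(3, 3)))
    specs = [
        LayerSpec("linear", activation="tanh", channels_out=3),
        LayerSpec("linear", channels_out=3),
    ]
    net = Network(specs, (4,), seed=3, dtype=np.float64)
    net.params[1] = q
    d = dtpmod.DTPNetwork(net, seed=3)
    d.g[1].V = q.T.copy()  # exact inverse of the linear top stage
    x = np.random.default_rng(1).normal(size=(5, 4))
    tr = net.forward(x)
    grad = np.random.default_rng(2).normal(size=tr.output.shape)
    targets = dtpmod.compute_targets(d, tr, grad, eta=0.1)
    assert np.allclose(targets[0], d.g[1](targets[1]), atol=1e-12)


def test_inverse_loss_zero_for_identity_pair():
    specs = [
        LayerSpec("linear", channels_out=4, activation="none"),
        LayerSpec("linear", channels_out=4),
    ]
    net = Network(specs, (4,), seed=0, dtype=np.float64)
    net.params[0] = np.eye(4)
    net.params[1] = np.eye(4)
    d = dtpmod.DTPNetwork(net, inverse_lr=0.1, seed=0)
    d.g[1].V = np.eye(4)
    x = np.random.default_rng(3).normal(size=(6, 4))
    tr = net.forward(x)
    v_before = d.g[1].V.copy()
    inv = dtpmod.train_inverses(d, tr)
    assert inv[1] == pytest.approx(0.0)
    assert np.allclose(d.g[1].V, v_before)  # zero loss, zero update


def test_inverse_loss_decreases_on_fixed_linear_stage():
    """Repeated SGD on the reconstruction loss of a linear toy stage is a
    convex least-squares descent: strictly decreasing over 50 steps."""
    net = two_stage_linear(seed=5)
    d = dtpmod.DTPNetwork(net, inverse_lr=0.05, seed=5)
    x = np.random.default_rng(4).normal(size=(20, 4))
    tr = net.forward(x)
    hist = [dtpmod.train_inverses(d, tr)[1] for _ in range(50)]
    assert all(b < a for a, b in zip(hist, hist[1:]))


def test_deconv_inverse_gradient_matches_finite_differences(rng):
    """Reconstruction-loss gradient of the strided deconvolution."""
    specs = [
        LayerSpec("conv", activation="tanh", channels_out=3, kernel=3),
        LayerSpec("maxpool", pool_size=2),
        LayerSpec("conv", activation="none", channels_out=2, kernel=3),
        LayerSpec("maxpool", pool_size=2),
        LayerSpec("flatten"),
        LayerSpec("linear", channels_out=4),
    ]
    net = Network(specs, (1, 8, 8), seed=6, dtype=np.float64)
    d = dtpmod.DTPNetwork(net, seed=6)
    x = rng.uniform(size=(2, 1, 8, 8))
    tr = net.forward(x)
    si = 1  # conv+pool stage with a strided deconv inverse
    g = d.g[si]
    z = d.stage_outputs(tr)[si]
    x_in = d.stage_input(tr, si)
    n = x.shape[0]

    def loss():
        r = g(z) - x_in
        return float((r * r).sum() / n)

    r = g(z) - x_in
    grad = g.grad(z, (2.0 / n) * r)
    flat = [np.unravel_index(k, g.V.shape)
            for k in rng.choice(g.V.size, size=10, replace=False)]
    fd = finite_difference(loss, g.V, flat)
    for k, v in fd.items():
        assert grad[k] == pytest.approx(v, rel=1e-6, abs=1e-9)


def test_two_stage_linear_hand_unrolled_step():
    """One full single-step pass on a two-stage linear toy matches manual
    arithmetic of the algorithm (inverse step, targets, forward steps)."""
    net = two_stage_linear(seed=7)
    flr, ilr, eta = 0.02, 0.05, 0.02
    d = dtpmod.DTPNetwork(net, forward_lr=flr, inverse_lr=ilr, seed=7)
    rng = np.random.default_rng(8)
    x0 = rng.normal(size=(6, 4))
    w1 = net.params[0].copy()
    w2 = net.params[1].copy()
    v2 = d.g[1].V.copy()
    grad_top = rng.normal(size=(6, 2))

    # --- manual unroll -----------------------------------------------
    h1 = x0 @ w1.T
    x1 = np.tanh(h1)
    x2 = x1 @ w2.T
    n = 6.0
    # inverse step on g_2
    recon = x2 @ v2.T
    r = recon - x1
    v2_new = v2 - ilr * ((2.0 / n) * r).T @ x2
    # targets with the updated inverse
    xhat2 = x2 - eta * grad_top
    xhat1 = x1 + (xhat2 @ v2_new.T - x2 @ v2_new.T)
    # forward updates
    diff1 = x1 - xhat1
    delta1 = ((2.0 / n) * diff1) * (1 - x1**2)
    w1_new = w1 - flr * (delta1.T @ x0)
    w2_new = w2 - flr * (grad_top.T @ x1)

    # --- implementation ----------------------------------------------
    tr = net.forward(x0)
    dtpmod.train_inverses(d, tr)
    targets = dtpmod.compute_targets(d, tr, grad_top, eta=eta)
    dtpmod.update_forward_stages(d, tr, targets, grad_top)

    assert np.allclose(d.g[1].V, v2_new, atol=1e-12)
    assert np.allclose(targets[0], xhat1, atol=1e-12)
    assert np.allclose(net.params[0], w1_new, atol=1e-12)
    assert np.allclose(net.params[1], w2_new, atol=1e-12)


def test_stage_updates_never_read_weights_above(toy_net, rng):
    """Asymmetric-connection contract, asserted via access tracing."""
    d = dtpmod.DTPNetwork(toy_net, seed=9)
    tr = toy_net.forward(rng.uniform(size=(3, 2, 8, 8)))
    grad = rng.normal(size=tr.output.shape)
    targets = dtpmod.compute_targets(d, tr, grad)
    with toy_net.trace_access() as log:
        dtpmod.update_forward_stages(d, tr, targets, grad)
    stage_ranges = {si: range(s0, s1) for si, (s0, s1) in enumerate(d.stages)}
    assert log, "update phase must read stage parameters"
    for mark, layer, block in log:
        assert mark is not None and mark[0] == "update"
        si = mark[1]
        assert layer in stage_ranges[si], (
            f"stage {si} update read {block}_{layer} outside its own range"
        )


def test_dtp_training_reduces_hinge_loss_on_structured_data(tiny_dataset):
    """200 steps of single-step DTP on synthetic SSL data reduce the
    global contrastive hinge loss relative to initialization."""
    from biossl import experiments

    images = tiny_dataset.train[0]
    init_l, final_l, _ = experiments.train_combo(images, "dtp", "-", seed=1,
                                                 steps=200)
    assert final_l < init_l
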