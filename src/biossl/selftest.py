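"""Fast oracle suite tying the modules together.

Each check is an independent identity the implementation must satisfy:
the hand-derived hinge error signals against central finite differences,
the RF = BP symmetry limit, URF = BP under symmetric initialisation, and
the DTP target fixed points. Runs in well under a minute on one CPU.
"""

from __future__ import annotations

import numpy as np

from . import dtp as dtpmod
from . import feedback, losses, training
from .deformations import ViewBatch, negative_sets
from .model_core import LayerSpec, Network


def _toy_net(seed=0, dtype=np.float64):
    specs = [
        LayerSpec("conv", activation="none", channels_out=4, kernel=3),
        LayerSpec("maxpool", activation="tanh", pool_size=2),
        LayerSpec("conv", activation="hardtanh", channels_out=6, kernel=3),
        LayerSpec("flatten"),
        LayerSpec("linear", channels_out=5),
    ]
    return Network(specs, (2, 8, 8), seed=seed, dtype=dtype)


def check_gradient_oracle(n_instances=20, rtol=1e-4, rng=None):
    """Manual hinge error signals vs central differences (dim 64, n 8, T 5)."""
    rng = rng or np.random.default_rng(0)
    n, d, T = 8, 64, 5
    negs = negative_sets(n, T)
    worst = 0.0
    for _ in range(n_instances):
        cfg = losses.HingeLossConfig(m1=1.0, m2=3.0, T=T, block_gradient=False)
        e_a = rng.normal(size=(n, d))
        e_b = rng.normal(size=(n, d))
        err = losses.hinge_error_signals(e_a, e_b, negs, cfg)
        g_a, g_b = losses.embedding_gradients(err, negs, False)
        eps = 1e-5
        for arr, g in ((e_a, g_a), (e_b, g_b)):
            idx = rng.integers(0, n, size=10), rng.integers(0, d, size=10)
            for i, j in zip(*idx):
                o = arr[i, j]
                arr[i, j] = o + eps
                fp = losses.hinge_loss(e_a, e_b, negs, cfg)[0]
                arr[i, j] = o - eps
                fm = losses.hinge_loss(e_a, e_b, negs, cfg)[0]
                arr[i, j] = o
                fd = (fp - fm) / (2 * eps)
                worst = max(worst, abs(fd - g[i, j]) / max(1.0, abs(fd)))
    return worst < rtol, f"max rel err {worst:.2e}"


def check_rf_symmetry(seed=0, atol=1e-10):
    """RF with feedback set to the forward transposes equals BP."""
    net = _toy_net(seed)
    for l in net.trainable_layers:
        net.feedback[l] = (
            net.params[l].T.copy() if net.specs[l].kind == "linear"
            else net.params[l].copy()
        )
    rng = np.random.default_rng(seed + 1)
    x = rng.uniform(size=(4, 2, 8, 8))
    tr = net.forward(x)
    top = rng.normal(size=tr.output.shape)
    d_bp, _ = feedback.backward_errors(net, tr, top,
                                       feedback.FeedbackState(rule="BP"))
    d_rf, _ = feedback.backward_errors(net, tr, top,
                                       feedback.FeedbackState(rule="RF"))
    worst = max(np.abs(d_bp[l] - d_rf[l]).max() for l in d_bp)
    return worst < atol, f"max delta diff {worst:.2e}"


def check_urf_equals_bp(steps=30, seed=0, atol=1e-10):
    """URF from symmetric initialisation tracks BP step for step."""
    n, T = 4, 2
    negs = negative_sets(n, T)
    cfg = losses.HingeLossConfig(m1=0.2, m2=1.0, T=T, block_gradient=True)

    def run(rule, sym):
        net = _toy_net(seed)
        if sym:
            for l in net.trainable_layers:
                net.feedback[l] = (
                    net.params[l].T.copy() if net.specs[l].kind == "linear"
                    else net.params[l].copy()
                )
        fb = feedback.FeedbackState(rule=rule, learning_rate=0.01)
        rng = np.random.default_rng(seed + 2)
        for _ in range(steps):
            a = rng.uniform(size=(n, 2, 8, 8))
            b = rng.uniform(size=(n, 2, 8, 8))
            training.hinge_ssl_step(net, ViewBatch(a, b, negs), cfg, fb)
        return net

    nb, nu = run("BP", False), run("URF", True)
    worst = max(
        np.abs(nb.params[l] - nu.params[l]).max() for l in nb.trainable_layers
    )
    return worst < atol, f"max weight diff {worst:.2e}"


def check_dtp_fixed_point(seed=0):
    """Zero top gradient: targets equal activations, local losses exactly 0."""
    net = _toy_net(seed)
    d = dtpmod.DTPNetwork(net, forward_lr=0.01, inverse_lr=0.01, seed=seed)
    rng = np.random.default_rng(seed + 3)
    x = rng.uniform(size=(4, 2, 8, 8))
    tr = net.forward(x)
    zero = np.zeros_like(tr.output)
    targets = dtpmod.compute_targets(d, tr, zero)
    outs = d.stage_outputs(tr)
    dev = max(np.abs(targets[s] - outs[s]).max() for s in targets)
    local = dtpmod.update_forward_stages(d, tr, targets, zero)
    loc = max(v for v in local.values() if v is not None)
    ok = dev == 0.0 and loc == 0.0
    return ok, f"target dev {dev:.2e}, max local loss {loc:.2e}"


CHECKS = [
    ("hinge gradient oracle", check_gradient_oracle),
    ("RF symmetry limit", check_rf_symmetry),
    ("URF equals BP", check_urf_equals_bp),
    ("DTP fixed point", check_dtp_fixed_point),
]


def run_selftest(echo=print) -> bool:
    all_ok = True
    for name, fn in CHECKS:
        ok, detail = fn()
        all_ok &= ok
        echo(f"{'PASS' if ok else 'FAIL'}  {name:24s} {detail}")
    return all_ok
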