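"""Contrastive hinge loss, its closed-form error signals, and the SimCLR
baseline, each checked against independent straight-line oracles."""

import numpy as np
import pytest

from biossl.deformations import negative_sets
from biossl.losses import (
    ErrorSignals,
    HingeLossConfig,
    SimCLRConfig,
    embedding_gradients,
    hinge_error_signals,
    hinge_loss,
    simclr_loss,
    top_layer_update,
)
from conftest import finite_difference


def worked_example():
    """Single active anchor: x^A=(2,0), x^B=(0.5,0), negative (1,0)."""
    emb_a = np.array([[2.0, 0.0], [50.0, 50.0]])
    emb_b = np.array([[0.5, 0.0], [1.0, 0.0]])
    negs = np.array([[1], [0]])
    cfg = HingeLossConfig(m1=1.0, m2=3.0, T=1)
    return emb_a, emb_b, negs, cfg


def test_worked_example_loss_terms():
    emb_a, emb_b, negs, cfg = worked_example()
    loss, bd = hinge_loss(emb_a, emb_b, negs, cfg)
    assert bd["pos_terms"][0] == pytest.approx(0.5)
    assert bd["neg_terms"][0, 0] == pytest.approx(2.0)
    assert bd["pos_terms"][0] + bd["neg_terms"][0, 0] == pytest.approx(2.5)


def test_worked_example_error_signals():
    emb_a, emb_b, negs, cfg = worked_example()
    err = hinge_error_signals(emb_a, emb_b, negs, cfg)
    assert np.array_equal(err.delta_B[0], [-1.0, 0.0])
    assert np.array_equal(err.delta_neg[0, 0], [1.0, 0.0])
    assert np.array_equal(err.delta_A[0], [0.0, 0.0])


def test_identical_positives_and_distant_negatives_zero_loss():
    emb = np.array([[0.0, 0.0], [10.0, 10.0], [-10.0, 10.0]])
    negs = negative_sets(3, 2)
    cfg = HingeLossConfig(m1=1.0, m2=3.0, T=2)
    loss, _ = hinge_loss(emb, emb.copy(), negs, cfg)
    assert loss == 0.0
    err = hinge_error_signals(emb, emb.copy(), negs, cfg)
    assert np.all(err.delta_A == 0) and np.all(err.delta_B == 0)
    assert np.all(err.delta_neg == 0)


def test_negative_exactly_at_margin_contributes_zero():
    emb_a = np.array([[0.0, 0.0], [3.0, 0.0]])
    emb_b = np.array([[0.0, 0.0], [3.0, 0.0]])  # negative at distance m2 = 3
    negs = np.array([[1], [0]])
    cfg = HingeLossConfig(m1=1.0, m2=3.0, T=1)
    loss, bd = hinge_loss(emb_a, emb_b, negs, cfg)
    assert loss == 0.0
    err = hinge_error_signals(emb_a, emb_b, negs, cfg)
    assert np.all(err.delta_neg == 0)  # strict indicator: boundary inactive


@pytest.mark.parametrize("block", [False, True])
def test_error_signals_match_central_differences(rng, block):
    """Off hinge boundaries, the sign-and-indicator error signals equal the
    numerical gradient of the loss w.r.t. the embeddings."""
    n, d, T = 8, 16, 5
    negs = negative_sets(n, T)
    cfg = HingeLossConfig(m1=1.0, m2=3.0, T=T, block_gradient=block)
    emb_a = rng.normal(size=(n, d))
    emb_b = rng.normal(size=(n, d))
    err = hinge_error_signals(emb_a, emb_b, negs, cfg)
    g_a, g_b = embedding_gradients(err, negs, block)

    def f():
        return hinge_loss(emb_a, emb_b, negs, cfg)[0]

    idx = [(i, j) for i in range(n) for j in rng.integers(0, d, size=3)]
    fd_b = finite_difference(f, emb_b, idx)
    for k, v in fd_b.items():
        assert g_b[k] == pytest.approx(v, abs=1e-4)
    if not block:
        fd_a = finite_difference(f, emb_a, idx)
        for k, v in fd_a.items():
            assert g_a[k] == pytest.approx(v, abs=1e-4)
    else:
        assert np.all(g_a == 0)


def test_top_layer_update_matches_finite_differences(rng):
    """The Hebbian outer-product update equals the numerical gradient of
    the composed loss w.r.t. the top weight matrix."""
    n, d, p, T = 6, 8, 10, 3
    negs = negative_sets(n, T)
    x_a = rng.normal(size=(n, p))
    x_b = rng.normal(size=(n, p))
    w = rng.normal(size=(d, p)) * 0.3
    for block in (False, True):
        cfg = HingeLossConfig(m1=1.0, m2=3.0, T=T, block_gradient=block)

        def f():
            ea = x_a @ w.T
            eb = x_b @ w.T
            if block:
                # anchor branch fixed at its current value (short-term memory)
                ea = x_a @ w0.T
            return hinge_loss(ea, eb, negs, cfg)[0]

        w0 = w.copy()
        err = hinge_error_signals(x_a @ w.T, x_b @ w.T, negs, cfg)
        g = top_layer_update(err, x_a, x_b, negs, cfg)
        idx = [(i, j) for i in rng.integers(0, d, 5) for j in rng.integers(0, p, 3)]
        fd = finite_difference(f, w, idx)
        for k, v in fd.items():
            assert g[k] == pytest.approx(v, rel=1e-4, abs=1e-6)


def test_blocking_differs_exactly_by_anchor_outer_product(rng):
    n, d, p, T = 5, 6, 7, 2
    negs = negative_sets(n, T)
    x_a, x_b = rng.normal(size=(n, p)), rng.normal(size=(n, p))
    e_a, e_b = rng.normal(size=(n, d)), rng.normal(size=(n, d))
    err = hinge_error_signals(e_a, e_b, negs, HingeLossConfig(m1=1, m2=3, T=T))
    g_full = top_layer_update(err, x_a, x_b, negs,
                              HingeLossConfig(m1=1, m2=3, T=T, block_gradient=False))
    g_block = top_layer_update(err, x_a, x_b, negs,
                               HingeLossConfig(m1=1, m2=3, T=T, block_gradient=True))
    assert np.allclose(g_full - g_block, err.delta_A.T @ x_a)


def test_zero_error_signals_give_zero_update(rng):
    n, d, p = 3, 4, 5
    err = ErrorSignals(np.zeros((n, d)), np.zeros((n, d)), np.zeros((n, 1, d)))
    negs = negative_sets(n, 1)
    g = top_layer_update(err, rng.normal(size=(n, p)), rng.normal(size=(n, p)),
                         negs, HingeLossConfig(m1=1, m2=3, T=1))
    assert np.all(g == 0)


def test_error_signal_locality(rng):
    """delta_B at coordinate i depends on other coordinates only through
    the scalar distance indicators."""
    n, d, T = 4, 10, 2
    negs = negative_sets(n, T)
    cfg = HingeLossConfig(m1=1.0, m2=30.0, T=T)  # indicators pinned active
    e_a = rng.normal(size=(n, d)) * 10
    e_b = rng.normal(size=(n, d))
    err1 = hinge_error_signals(e_a, e_b, negs, cfg)
    e_b2 = e_b.copy()
    e_b2[:, 3] += 0.01  # perturb coordinate 3 without flipping indicators
    err2 = hinge_error_signals(e_a, e_b2, negs, cfg)
    mask = np.ones(d, dtype=bool)
    mask[3] = False
    assert np.array_equal(err1.delta_B[:, mask], err2.delta_B[:, mask])


def test_hinge_loss_invariant_to_joint_coordinate_permutation(rng):
    n, d, T = 6, 12, 3
    negs = negative_sets(n, T)
    cfg = HingeLossConfig(m1=1.0, m2=3.0, T=T)
    e_a, e_b = rng.normal(size=(n, d)), rng.normal(size=(n, d))
    perm = rng.permutation(d)
    l1, _ = hinge_loss(e_a, e_b, negs, cfg)
    l2, _ = hinge_loss(e_a[:, perm], e_b[:, perm], negs, cfg)
    assert l1 == pytest.approx(l2)


def test_hinge_loss_nonnegative_and_zero_iff_margins_met(rng):
    n, T = 8, 3
    negs = negative_sets(n, T)
    cfg = HingeLossConfig(m1=1.0, m2=3.0, T=T)
    for _ in range(20):
        e_a = rng.normal(size=(n, 6))
        e_b = rng.normal(size=(n, 6))
        loss, bd = hinge_loss(e_a, e_b, negs, cfg)
        assert loss >= 0.0
        within = np.all(bd["pos_distances"] <= cfg.m1) and np.all(
            bd["neg_distances"] >= cfg.m2
        )
        assert (loss == 0.0) == within


def test_mismatched_embedding_shapes_rejected(rng):
    with pytest.raises(ValueError, match="shapes"):
        hinge_loss(rng.normal(size=(3, 4)), rng.normal(size=(3, 5)),
                   negative_sets(3, 1), HingeLossConfig(T=1))


# -- SimCLR baseline -------------------------------------------------------

def naive_simclr(emb_a, emb_b, tau):
    """Straight-line transcription of the symmetric NT-Xent loss."""
    def sim(u, v):
        return u @ v / (np.linalg.norm(u) * np.linalg.norm(v))

    n = emb_a.shape[0]
    total = 0.0
    for first, second in ((emb_a, emb_b), (emb_b, emb_a)):
        for s in range(n):
            num = np.exp(sim(first[s], second[s]) / tau)
            den = sum(
                np.exp(sim(first[s], first[t]) / tau) for t in range(n) if t != s
            ) + sum(np.exp(sim(first[s], second[t]) / tau) for t in range(n))
            total -= np.log(num / den)
    return total


def test_simclr_equal_similarities_closed_form():
    """With all pairwise cosines equal each of the 4 terms is -log(1/3)."""
    emb = np.array([[1.0, 0.0], [1.0, 0.0]])
    assert simclr_loss(emb, emb.copy(), SimCLRConfig(tau=0.1)) == pytest.approx(
        4 * np.log(3.0)
    )


def test_simclr_matches_straight_line_oracle(rng):
    emb_a = rng.normal(size=(4, 8))
    emb_b = rng.normal(size=(4, 8))
    cfg = SimCLRConfig(tau=0.25)
    assert simclr_loss(emb_a, emb_b, cfg) == pytest.approx(
        naive_simclr(emb_a, emb_b, cfg.tau), rel=1e-10
    )


def test_simclr_scale_invariance(rng):
    emb_a = rng.normal(size=(5, 6))
    emb_b = rng.normal(size=(5, 6))
    cfg = SimCLRConfig(tau=0.5)
    assert simclr_loss(emb_a, emb_b, cfg) == pytest.approx(
        simclr_loss(emb_a * 7.3, emb_b * 7.3, cfg)
    )


def test_simclr_zero_norm_rejected(rng):
    emb = rng.normal(size=(3, 4))
    bad = emb.copy()
    bad[1] = 0.0
    with pytest.raises(FloatingPointError):
        simclr_loss(bad, emb, SimCLRConfig(tau=0.1))
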