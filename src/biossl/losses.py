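"""Contrastive losses and their hand-derived error signals.

The central object is the *contrastive hinge loss*. For a batch of paired
embeddings ``x_s^A, x_s^B`` (two deformed views of image ``s``) and
per-anchor negative sets ``N_s`` drawn from the B branch,

    L = sum_s [ ||x_s^A - x_s^B||_1 - m1 ]_+
        + sum_s sum_{t in N_s} [ m2 - ||x_s^A - x_t^B||_1 ]_+

Only positives further apart than the margin ``m1`` and negatives closer
than the margin ``m2`` contribute. The gradient of this loss with respect
to the embeddings is a sum of sign terms gated by 0/1 indicators — no
normalisation, inner products or divisions — so the top-layer weight update
is a plain Hebbian product of an error signal and the pre-synaptic
activity. With *gradient blocking* the anchor-branch term is dropped: the
anchor embedding acts as a short-term memory trace that shapes the error
signal but receives no update itself.

The SimCLR loss (normalised-temperature cross-entropy over cosine
similarities) is provided as a baseline for comparison; it is evaluated,
not trained, in this package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class HingeLossConfig:
    m1: float = 1.0  # positive-pair distance margin
    m2: float = 3.0  # negative-pair distance margin
    T: int = 5  # negatives per anchor
    block_gradient: bool = True

    def __post_init__(self):
        if self.m1 < 0 or self.m2 <= 0:
            raise ValueError("need m1 >= 0 and m2 > 0")


@dataclass
class SimCLRConfig:
    tau: float = 0.1

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("temperature tau must be positive")


@dataclass
class ErrorSignals:
    """Top-layer error vectors of the hinge loss.

    ``delta_A``: (n, d) anchor-branch signal; ``delta_B``: (n, d)
    positive-branch signal; ``delta_neg``: (n, T, d) per-(anchor, negative)
    signals. Each component is an integer-valued sum of gated signs.
    """

    delta_A: np.ndarray
    delta_B: np.ndarray
    delta_neg: np.ndarray


def _check_pair(emb_A, emb_B):
    if emb_A.shape != emb_B.shape:
        raise ValueError(f"embedding shapes differ: {emb_A.shape} vs {emb_B.shape}")


def _gather_negatives(emb_B: np.ndarray, negatives: np.ndarray) -> np.ndarray:
    """(n, T, d) array of negative embeddings x_t^B for each anchor."""
    negatives = np.asarray(negatives)
    if negatives.ndim != 2:
        raise ValueError("negative sets must form an (n, T) index array")
    return emb_B[negatives]


def hinge_loss(emb_A, emb_B, negatives, cfg: HingeLossConfig):
    """Contrastive hinge loss (batch sum) with a per-term breakdown.

    Returns ``(loss, breakdown)`` where ``breakdown`` exposes the per-anchor
    positive terms, per-(anchor, negative) terms and active-pair counts.
    """
    emb_A = np.asarray(emb_A, dtype=np.float64)
    emb_B = np.asarray(emb_B, dtype=np.float64)
    _check_pair(emb_A, emb_B)
    d_pos = np.abs(emb_A - emb_B).sum(axis=1)  # (n,)
    neg = _gather_negatives(emb_B, negatives)  # (n, T, d)
    d_neg = np.abs(emb_A[:, None, :] - neg).sum(axis=2)  # (n, T)
    pos_terms = np.maximum(d_pos - cfg.m1, 0.0)
    neg_terms = np.maximum(cfg.m2 - d_neg, 0.0)
    loss = float(pos_terms.sum() + neg_terms.sum())
    breakdown = {
        "pos_terms": pos_terms,
        "neg_terms": neg_terms,
        "pos_distances": d_pos,
        "neg_distances": d_neg,
        "n_active_pos": int((d_pos > cfg.m1).sum()),
        "n_active_neg": int((d_neg < cfg.m2).sum()),
    }
    return loss, breakdown


def hinge_error_signals(emb_A, emb_B, negatives, cfg: HingeLossConfig) -> ErrorSignals:
    """Closed-form error signals of the hinge loss.

    delta_A_i =  1{||xA-xB||_1 > m1} sgn(xA_i - xB_i)
               - sum_t 1{||xA-xt||_1 < m2} sgn(xA_i - xt_i)
    delta_B_i = -1{||xA-xB||_1 > m1} sgn(xA_i - xB_i)
    delta_t_i =  1{||xA-xt||_1 < m2} sgn(xA_i - xt_i)

    with sgn(0) = 0. These equal the (sub)gradients of the loss with
    respect to the three embedding groups.
    """
    emb_A = np.asarray(emb_A, dtype=np.float64)
    emb_B = np.asarray(emb_B, dtype=np.float64)
    _check_pair(emb_A, emb_B)
    negatives = np.asarray(negatives)
    diff_pos = emb_A - emb_B
    d_pos = np.abs(diff_pos).sum(axis=1)
    pos_active = (d_pos > cfg.m1)[:, None].astype(np.float64)  # strict, as is the hinge
    sgn_pos = np.sign(diff_pos)

    neg = _gather_negatives(emb_B, negatives)
    diff_neg = emb_A[:, None, :] - neg
    d_neg = np.abs(diff_neg).sum(axis=2)
    neg_active = (d_neg < cfg.m2)[:, :, None].astype(np.float64)
    sgn_neg = np.sign(diff_neg)

    delta_B = -pos_active * sgn_pos
    delta_neg = neg_active * sgn_neg
    delta_A = pos_active * sgn_pos - delta_neg.sum(axis=1)
    return ErrorSignals(delta_A=delta_A, delta_B=delta_B, delta_neg=delta_neg)


def embedding_gradients(err: ErrorSignals, negatives, block_gradient: bool):
    """Aggregate error signals into gradients w.r.t. the two view batches.

    The negatives are rows of the B batch, so each B embedding accumulates
    its positive-partner signal plus every signal it receives while serving
    as a negative for other anchors. With ``block_gradient`` the A-branch
    gradient is zero (the anchor lives in short-term memory only).
    """
    negatives = np.asarray(negatives)
    grad_B = err.delta_B.copy()
    n, T = negatives.shape
    flat_idx = negatives.reshape(-1)
    np.add.at(grad_B, flat_idx, err.delta_neg.reshape(n * T, -1))
    grad_A = np.zeros_like(err.delta_A) if block_gradient else err.delta_A.copy()
    return grad_A, grad_B


def top_layer_update(err: ErrorSignals, x_prev_A, x_prev_B, negatives,
                     cfg: HingeLossConfig) -> np.ndarray:
    """Hebbian gradient of the hinge loss w.r.t. the top weight matrix.

    Returns ``G = dL/dW_L``; gradient descent applies ``W_L -= lr * G``.
    Each contribution is an outer product of a top-layer error signal and
    the pre-synaptic activity of its branch:

        G = delta_A x_{L-1}^A^T + delta_B x_{L-1}^B^T
            + sum_t delta_t x_{t,L-1}^B^T

    With gradient blocking the anchor (A) term is dropped.
    """
    x_prev_A = np.asarray(x_prev_A, dtype=np.float64)
    x_prev_B = np.asarray(x_prev_B, dtype=np.float64)
    if x_prev_A.shape != x_prev_B.shape:
        raise ValueError("pre-synaptic traces of the two branches differ in shape")
    negatives = np.asarray(negatives)
    g = err.delta_B.T @ x_prev_B
    neg_prev = x_prev_B[negatives]  # (n, T, d_prev)
    g += np.einsum("ntd,ntp->dp", err.delta_neg, neg_prev)
    if not cfg.block_gradient:
        g += err.delta_A.T @ x_prev_A
    return g


def simclr_loss(emb_A, emb_B, cfg: SimCLRConfig) -> float:
    """Symmetric normalised-temperature cross-entropy baseline.

    For each anchor the denominator runs over the other same-branch
    embeddings (excluding the anchor itself) plus all opposite-branch
    embeddings, with cosine similarity scaled by ``1/tau``.
    """
    emb_A = np.asarray(emb_A, dtype=np.float64)
    emb_B = np.asarray(emb_B, dtype=np.float64)
    _check_pair(emb_A, emb_B)
    n = emb_A.shape[0]
    if n < 2:
        raise ValueError("SimCLR loss needs batch size >= 2")
    na = np.linalg.norm(emb_A, axis=1)
    nb = np.linalg.norm(emb_B, axis=1)
    if np.any(na == 0) or np.any(nb == 0):
        raise FloatingPointError("zero-norm embedding: cosine similarity undefined")
    ua, ub = emb_A / na[:, None], emb_B / nb[:, None]

    def direction(u, v):
        # anchor batch u against same-branch u and opposite-branch v
        s_same = (u @ u.T) / cfg.tau
        s_cross = (u @ v.T) / cfg.tau
        m = max(s_same.max(), s_cross.max())  # log-sum-exp stabilisation
        e_same = np.exp(s_same - m)
        np.fill_diagonal(e_same, 0.0)  # exclude the anchor itself
        e_cross = np.exp(s_cross - m)
        denom = e_same.sum(axis=1) + e_cross.sum(axis=1)
        num = np.exp(np.diag(s_cross) - m)
        return -np.log(num / denom).sum()

    return float(direction(ua, ub) + direction(ub, ua))
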