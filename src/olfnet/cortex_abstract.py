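"""Abstract cortical evaluation path: support, activation, recall.

A minicolumn (MC) *j* receives feedforward support ``s_j = Σ_i w_ij ξ_i``
from MT cells, turns it into an output activation
``o_j = exp(β_j + s_j)`` when the support is positive (0 otherwise), and
the activations of the MCs inside one hypercolumn (HC) are
half-normalized so they can be read as probabilities of perceiving a
feature.  Recurrent MC→MC weights (absent within an HC) and a supervised
readout layer (one indicator unit per training label) are learned with the
same Hebbian–Bayesian rule from the training activations.  Classification
= argmax over readout supports; the recurrent relaxation loop is the
rate-level stand-in for the spiking attractor dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .selforg import (
    BCPNNNet,
    activation_probabilities,
    bcpnn_bias,
    bcpnn_weights,
    half_normalize,
    joint_probabilities,
)

DEFAULT_N_ITER = 3
#: Gain on the recurrent support term during recall.  The recurrent
#: log-odds weights live on a much larger scale than the feedforward
#: support (they sum full log-probabilities over 12 hypercolumns), so the
#: attractor correction is applied as a fractional nudge per iteration
#: rather than at full strength — the rate-level analogue of the modest
#: recurrent conductances of the spiking network.
DEFAULT_REC_GAIN = 0.05


@dataclass
class RecallResult:
    """Classification outcome of one panel presentation."""

    readout_support: np.ndarray  # (n_readout, n_patterns)
    labels: np.ndarray  # (n_patterns,) argmax readout per pattern
    ambiguous: np.ndarray  # boolean; tie at the top, broken to lowest index
    o_prime: np.ndarray  # final half-normalized MC activations


def feedforward_support(w_ff: np.ndarray, xi: np.ndarray) -> np.ndarray:
    """s = Σ_i w_ij ξ_i; ``w_ff`` is (n_pre, n_post), ``xi`` (n_pre, P)."""
    w_ff = np.asarray(w_ff, dtype=float)
    xi = np.asarray(xi, dtype=float)
    if w_ff.shape[0] != xi.shape[0]:
        raise ValueError(
            f"weight rows ({w_ff.shape[0]}) != presynaptic units ({xi.shape[0]})")
    return w_ff.T @ xi


def output_activation(s: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """o = exp(β + s) where s > 0, else 0 (strict threshold)."""
    s = np.asarray(s, dtype=float)
    beta = np.asarray(beta, dtype=float)
    b = beta[:, None] if s.ndim == 2 else beta
    with np.errstate(over="ignore"):
        return np.where(s > 0, np.exp(b + s), 0.0)


def _activate_and_normalize(
    s: np.ndarray, beta: np.ndarray, hc_index: np.ndarray
) -> np.ndarray:
    """o' = half-normalized exp(β+s), computed per HC in log space.

    Equivalent to ``half_normalize(output_activation(s, beta), hc_index)``
    but immune to overflow: whenever an HC's activation sum exceeds 1 the
    result is that HC's softmax, which is evaluated max-subtracted.
    """
    s = np.asarray(s, dtype=float)
    lo = np.where(s > 0, beta[:, None] + s, -np.inf)  # log o
    n_hc = int(hc_index.max()) + 1
    o_prime = np.zeros_like(s)
    for h in range(n_hc):
        rows = hc_index == h
        lh = lo[rows]
        mx = lh.max(axis=0)
        finite = np.isfinite(mx)
        if not np.any(finite):
            continue
        ex = np.exp(lh[:, finite] - mx[finite])
        logsum = mx[finite] + np.log(ex.sum(axis=0))
        with np.errstate(over="ignore"):
            norm = np.where(logsum > 0, ex / ex.sum(axis=0),
                            np.exp(lh[:, finite]))
        block = np.zeros_like(lh)
        block[:, finite] = norm
        o_prime[rows] = block
    return o_prime


def learn_recurrent(
    o_prime: np.ndarray, hc_index: np.ndarray, n_patterns: int
) -> BCPNNNet:
    """BCPNN recurrent MC→MC weights from training activations.

    MCs of the same HC are never connected (their competition is handled by
    the half-normalization / basket inhibition), so all within-HC entries —
    including self-connections — are forced to 0.
    """
    p, p_joint = activation_probabilities(o_prime)
    w = bcpnn_weights(p, p, p_joint, n_patterns)
    hc_index = np.asarray(hc_index)
    same_hc = hc_index[:, None] == hc_index[None, :]
    w[same_hc] = 0.0
    return BCPNNNet(w, bcpnn_bias(p, n_patterns), n_patterns)


def learn_readout(
    o_prime: np.ndarray, labels: np.ndarray | None = None, n_readout: int | None = None
) -> BCPNNNet:
    """Supervised BCPNN readout: one indicator unit per training label.

    The supervisor sets readout *j* active exactly in the patterns carrying
    label *j* (for the classical one-label-per-pattern case this is the
    identity, p_j = 1/N_p).
    """
    o_prime = np.asarray(o_prime, dtype=float)
    n_p = o_prime.shape[1]
    labels = np.arange(n_p) if labels is None else np.asarray(labels, dtype=int)
    n_readout = int(labels.max()) + 1 if n_readout is None else n_readout
    supervisor = np.zeros((n_readout, n_p))
    supervisor[labels, np.arange(n_p)] = 1.0
    p_pre = o_prime.mean(axis=1)
    p_post = supervisor.mean(axis=1)
    p_joint = joint_probabilities(o_prime, supervisor)
    w = bcpnn_weights(p_pre, p_post, p_joint, n_p)
    return BCPNNNet(w, bcpnn_bias(p_post, n_p), n_p)


def recall(
    xi_test: np.ndarray,
    ff_net: BCPNNNet,
    rec_net: BCPNNNet | None,
    ro_net: BCPNNNet,
    hc_index: np.ndarray,
    n_iter: int = DEFAULT_N_ITER,
    rec_gain: float = DEFAULT_REC_GAIN,
) -> RecallResult:
    """Classify test patterns: feedforward pass, recurrent relaxation, readout.

    The MC state is initialized from the feedforward support alone and then
    relaxed ``n_iter`` times with ``s = s_ff + rec_gain * o'ᵀ w_rec``
    (``n_iter=0`` or ``rec_net=None`` reduces to pure feedforward
    classification).  Readout support is ``o'ᵀ w_ro + β_ro``; the label is
    the argmax, ties broken to the lowest index and flagged as ambiguous.
    """
    for net, name in ((ff_net, "feedforward"), (ro_net, "readout")):
        if net is None or net.w.size == 0:
            raise ValueError(f"{name} net is untrained")
    s_ff = feedforward_support(ff_net.w, xi_test)
    o_prime = _activate_and_normalize(s_ff, ff_net.beta, hc_index)
    if rec_net is not None:
        for _ in range(n_iter):
            s = s_ff + rec_gain * (rec_net.w.T @ o_prime)
            o_prime = _activate_and_normalize(s, ff_net.beta, hc_index)
    support = ro_net.w.T @ o_prime + ro_net.beta[:, None]
    labels = np.argmax(support, axis=0)
    top = support.max(axis=0)
    ambiguous = (support == top[None, :]).sum(axis=0) > 1
    return RecallResult(support, labels, ambiguous, o_prime)
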