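"""Temporal cycle-consistency (TCC) alignment loss.

Two trajectories of the same process, embedded frame by frame, should be
alignable: the soft nearest neighbour of frame ``u_i`` within sequence ``V``
should "cycle back" to frame ``i`` of ``U``.  Treating the frames of ``U`` as
classes turns this into a differentiable classification problem:

* ``alpha_j = softmax_j(-||u_i - v_j||^2 / tau)`` — soft-assignment of the
  reference frame onto ``V``;
* ``v~ = sum_j alpha_j v_j`` — the soft nearest neighbour;
* ``beta_k = softmax_k(-||v~ - u_k||^2 / tau)`` — the cycle-back
  distribution, whose cross-entropy against the index ``i`` is the loss.

During manifold training the loss is averaged over every reference frame of
both orderings of a trajectory pair, which encodes temporal context without
any stage labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor

__all__ = ["SoftAlignment", "soft_nearest_neighbor", "cycle_back_distribution",
           "tcc_loss", "tcc_loss_graph", "cycle_consistent_fraction"]


@dataclass
class SoftAlignment:
    """Soft nearest-neighbour weights and the resulting blended embedding."""

    alpha: np.ndarray
    v_tilde: np.ndarray


def _sqdist_graph(a: Tensor, B: Tensor) -> Tensor:
    """Squared Euclidean distances between rows of ``a`` and rows of ``B``."""
    diff = a.reshape(a.shape[0], 1, a.shape[1]) - B.reshape(1, B.shape[0], B.shape[1])
    return (diff**2).sum(axis=2)


def _check_seq(V: np.ndarray, name: str) -> np.ndarray:
    V = np.asarray(V, dtype=np.float64)
    if V.ndim == 1:
        V = V[:, None]
    if V.size == 0:
        raise ValueError(f"{name} must contain at least one frame")
    return V


def soft_nearest_neighbor(u_i: np.ndarray, V: np.ndarray,
                          temperature: float = 1.0) -> SoftAlignment:
    """Soft nearest neighbour of the reference embedding ``u_i`` in ``V``."""
    V = _check_seq(V, "V")
    u_i = np.asarray(u_i, dtype=np.float64).reshape(1, -1)
    if u_i.shape[1] != V.shape[1]:
        raise ValueError("embedding dimensions disagree")
    d2 = np.sum((u_i - V) ** 2, axis=1) / temperature
    d2 -= d2.min()
    alpha = np.exp(-d2)
    alpha /= alpha.sum()
    return SoftAlignment(alpha=alpha, v_tilde=alpha @ V)


def cycle_back_distribution(v_tilde: np.ndarray, U: np.ndarray,
                            temperature: float = 1.0) -> np.ndarray:
    """Distribution over the frames of ``U`` for the cycled-back embedding."""
    return soft_nearest_neighbor(v_tilde, U, temperature).alpha


def tcc_loss_graph(U: Tensor, V: Tensor, temperature: float = 1.0) -> Tensor:
    """Differentiable TCC loss between two embedding-sequence tensors.

    Mean over reference frames ``i`` of ``-log beta_i`` where ``beta`` is the
    cycle-back distribution of the soft nearest neighbour of ``u_i`` in ``V``.
    """
    log_alpha = (-_sqdist_graph(U, V) / temperature).log_softmax(axis=1)
    v_tilde = log_alpha.exp() @ V          # (T_u, dim)
    log_beta = (-_sqdist_graph(v_tilde, U) / temperature).log_softmax(axis=1)
    t = U.shape[0]
    return -log_beta[np.arange(t), np.arange(t)].mean()


def tcc_loss(U: np.ndarray, V: np.ndarray, temperature: float = 1.0) -> float:
    """TCC loss between two embedding sequences given as arrays."""
    U = _check_seq(U, "U")
    V = _check_seq(V, "V")
    if U.shape[0] < 2 or V.shape[0] < 2:
        raise ValueError("sequences must have at least two frames")
    if U.shape[1] != V.shape[1]:
        raise ValueError("embedding dimensions disagree")
    return float(tcc_loss_graph(Tensor(U), Tensor(V), temperature).data)


def cycle_consistent_fraction(U: np.ndarray, V: np.ndarray) -> float:
    """Diagnostic: fraction of frames of ``U`` whose hard nearest neighbour in
    ``V`` maps back to the same frame.  Not differentiable; evaluation only."""
    U = _check_seq(U, "U")
    V = _check_seq(V, "V")
    d_uv = ((U[:, None, :] - V[None, :, :]) ** 2).sum(axis=2)
    j = np.argmin(d_uv, axis=1)
    back = np.argmin(d_uv.T, axis=1)
    return float(np.mean(back[j] == np.arange(U.shape[0])))
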