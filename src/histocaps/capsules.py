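"""Capsule primitives and dynamic routing-by-agreement.

A capsule is a vector-valued unit: its direction encodes pose, its length
the probability that the entity it represents is present.  Lower-layer
capsules cast votes (linear predictions) for every parent capsule; an
iterative routing loop concentrates each lower capsule's coupling on the
parents that agree with its vote.

Shapes follow the convention ``(..., I, J, P)`` for prediction tensors —
arbitrary leading batch axes, I lower capsules, J parents, P parent dims —
so the same functions serve both unbatched unit tests and batched network
forward passes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import softmax

__all__ = [
    "RoutingState",
    "squash",
    "predict",
    "coupling_from_logits",
    "agreement",
    "dynamic_routing",
]

_NORM_EPS = 1e-9


def _as_float(a: np.ndarray) -> np.ndarray:
    """View as a floating array without up-casting float32 inputs."""
    a = np.asarray(a)
    return a if np.issubdtype(a.dtype, np.floating) else a.astype(float)


@dataclass
class RoutingState:
    """Full state of a finished routing loop (final-iteration values)."""

    logits: np.ndarray          # (..., I, J)  b_ij
    couplings: np.ndarray       # (..., I, J)  c_ij, rows over j sum to 1
    parent_inputs: np.ndarray   # (..., J, P)  s_j
    parent_outputs: np.ndarray  # (..., J, P)  v_j
    iterations: int


def squash(s: np.ndarray, axis: int = -1) -> np.ndarray:
    """Vector nonlinearity v = (|s|^2 / (1 + |s|^2)) * s / |s|.

    Preserves direction, maps the norm through r -> r^2/(1+r^2) so outputs
    lie strictly inside the unit ball; the zero vector maps to itself.
    """
    s = _as_float(s)
    sq = np.sum(s * s, axis=axis, keepdims=True)
    norm = np.sqrt(sq)
    scale = sq / (1.0 + sq)  # target norm |v| = r^2/(1+r^2)
    return s * scale / np.maximum(norm, _NORM_EPS)


def predict(u: np.ndarray, transform: np.ndarray) -> np.ndarray:
    """Per-pair votes u_hat[j|i] = W_ij @ u_i.

    ``u`` is (I, D), ``transform`` is (I, J, P, D); the result is (I, J, P).
    """
    u = _as_float(u)
    transform = _as_float(transform)
    if transform.shape[-1] != u.shape[-1] or transform.shape[0] != u.shape[0]:
        raise ValueError(
            f"transform {transform.shape} incompatible with u {u.shape}"
        )
    return np.einsum("ijpd,id->ijp", transform, u)


def coupling_from_logits(logits: np.ndarray) -> np.ndarray:
    """Softmax over the parent axis (last): each lower capsule distributes a
    unit budget of coupling across parents."""
    return softmax(_as_float(logits), axis=-1)


def agreement(v: np.ndarray, u_hat: np.ndarray) -> np.ndarray:
    """Inner product a_ij = v_j . u_hat_{j|i} between a parent output and a
    vote for it."""
    v = _as_float(v)
    u_hat = _as_float(u_hat)
    if v.shape[-1] != u_hat.shape[-1]:
        raise ValueError(f"dim mismatch: {v.shape} vs {u_hat.shape}")
    return np.sum(v * u_hat, axis=-1)


def dynamic_routing(
    predictions: np.ndarray, iterations: int = 3
) -> tuple[np.ndarray, RoutingState]:
    """Routing-by-agreement over a (..., I, J, P) prediction tensor.

    Logits start at zero (uniform couplings).  Each iteration computes
    couplings c = softmax_j(b), parent inputs s_j = sum_i c_ij u_hat_{j|i},
    outputs v_j = squash(s_j), and — on every iteration but the last — the
    logit update b_ij += v_j . u_hat_{j|i}.

    Returns the final parent outputs (..., J, P) and the full state.
    """
    if iterations < 1:
        raise ValueError(f"iterations must be >= 1, got {iterations}")
    u_hat = _as_float(predictions)
    if u_hat.ndim < 3:
        raise ValueError("predictions must have shape (..., I, J, P)")
    b = np.zeros(u_hat.shape[:-1], dtype=u_hat.dtype)  # (..., I, J)
    c = s = v = None
    for it in range(iterations):
        c = coupling_from_logits(b)
        s = np.einsum("...ij,...ijp->...jp", c, u_hat)
        v = squash(s, axis=-1)
        if it < iterations - 1:
            b = b + np.einsum("...jp,...ijp->...ij", v, u_hat)
    state = RoutingState(
        logits=b, couplings=c, parent_inputs=s, parent_outputs=v,
        iterations=iterations,
    )
    return v, state
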