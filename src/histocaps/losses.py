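"""Threefold margin loss for class-capsule classification.

The classic capsule margin loss penalises, per class k, a true-class capsule
norm below m+ and (down-weighted by lambda) a wrong-class norm above m-.
Here three such hinges with progressively looser margins are evaluated on
the same class-capsule norms and summed, giving a graded penalty surface:

    l_f = T_k max(0, m_f+ - |v_k|)^2 + lambda_f (1 - T_k) max(0, |v_k| - m_f-)^2
    L   = sum_f l_f,   f = 1..3

with defaults (m+, m-, lambda) = (0.90, 0.10, 0.75), (0.80, 0.20, 0.55),
(0.70, 0.30, 0.35).  The loss is summed over classes and averaged over the
batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MarginFoldParams",
    "ThreefoldLossConfig",
    "margin_loss_fold",
    "threefold_total",
    "threefold_loss_and_grad",
]


@dataclass(frozen=True)
class MarginFoldParams:
    """One fold's margins: positive margin m+, negative margin m-, and the
    absent-class down-weight lambda."""

    m_plus: float
    m_minus: float
    lam: float

    def __post_init__(self) -> None:
        if not (0.0 < self.m_plus < 1.0 and 0.0 < self.m_minus < 1.0):
            raise ValueError("margins must lie in (0, 1)")
        if self.m_plus <= self.m_minus:
            raise ValueError("m_plus must exceed m_minus")
        if self.lam <= 0:
            raise ValueError("lam must be > 0")


def _default_folds() -> tuple[MarginFoldParams, ...]:
    return (
        MarginFoldParams(0.90, 0.10, 0.75),
        MarginFoldParams(0.80, 0.20, 0.55),
        MarginFoldParams(0.70, 0.30, 0.35),
    )


@dataclass(frozen=True)
class ThreefoldLossConfig:
    folds: tuple[MarginFoldParams, ...] = field(default_factory=_default_folds)

    def __post_init__(self) -> None:
        if len(self.folds) != 3:
            raise ValueError(f"exactly 3 folds required, got {len(self.folds)}")


def _validate(norms: np.ndarray, targets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    norms = np.atleast_2d(np.asarray(norms, dtype=float))
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    if norms.shape != targets.shape:
        raise ValueError(f"shape mismatch: norms {norms.shape} vs targets {targets.shape}")
    if np.any(norms < 0) or np.any(norms > 1):
        raise ValueError("capsule norms must lie in [0, 1]")
    return norms, targets


def margin_loss_fold(
    norms: np.ndarray, targets: np.ndarray, fold: MarginFoldParams
) -> float:
    """One fold's margin loss, summed over classes, averaged over the batch.

    ``norms`` and ``targets`` are (batch, classes); targets are one-hot.
    """
    norms, targets = _validate(norms, targets)
    pos = np.maximum(0.0, fold.m_plus - norms) ** 2
    neg = np.maximum(0.0, norms - fold.m_minus) ** 2
    per_class = targets * pos + fold.lam * (1.0 - targets) * neg
    return float(per_class.sum(axis=1).mean())


def threefold_total(
    norms: np.ndarray,
    targets: np.ndarray,
    config: ThreefoldLossConfig | None = None,
) -> float:
    """Sum of the three fold losses on the same class-capsule norms."""
    config = config or ThreefoldLossConfig()
    return sum(margin_loss_fold(norms, targets, f) for f in config.folds)


def threefold_loss_and_grad(
    vectors: np.ndarray,
    targets: np.ndarray,
    config: ThreefoldLossConfig | None = None,
) -> tuple[float, np.ndarray]:
    """Loss and its analytic gradient with respect to the capsule vectors.

    ``vectors`` is (batch, classes, dim).  The chain rule runs through the
    norm: dL/dv = (dL/d|v|) * v / |v|, with the zero vector's gradient taken
    as zero (both hinge derivatives vanish there only if m- > 0; the
    direction is undefined, so zero is the conservative subgradient choice).
    """
    config = config or ThreefoldLossConfig()
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 3:
        raise ValueError("vectors must be (batch, classes, dim)")
    norms = np.sqrt((vectors**2).sum(axis=2))
    norms_c, targets_c = _validate(norms, targets)
    batch = norms_c.shape[0]
    loss = 0.0
    dnorm = np.zeros_like(norms_c)
    for fold in config.folds:
        pos_gap = np.maximum(0.0, fold.m_plus - norms_c)
        neg_gap = np.maximum(0.0, norms_c - fold.m_minus)
        loss += float(
            (targets_c * pos_gap**2 + fold.lam * (1.0 - targets_c) * neg_gap**2)
            .sum(axis=1)
            .mean()
        )
        dnorm += (-2.0 * targets_c * pos_gap + 2.0 * fold.lam * (1.0 - targets_c) * neg_gap) / batch
    unit = vectors / np.maximum(norms, 1e-12)[..., None]
    return loss, dnorm[..., None] * unit
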