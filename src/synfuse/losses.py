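"""Prediction losses: binary cross-entropy, the symmetric Bernoulli KL of
R-drop, and their combination L = L_cross + alpha * L_KL.

Two parallel surfaces are provided. The float/array functions take
probabilities and implement the textbook formulas directly; they back the
analytic tests. The ``*_from_logits`` functions operate on autograd tensors
through softplus (log p = -softplus(-z), log(1-p) = -softplus(z)), so
training never evaluates log of a clamped probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor


@dataclass
class LossBreakdown:
    """L = cross + alpha * kl, averaged over the batch."""

    cross: float
    kl: float
    alpha: float

    @property
    def total(self) -> float:
        return self.cross + self.alpha * self.kl


def _check_prob(p, name: str = "probability") -> np.ndarray:
    arr = np.asarray(p, dtype=np.float64)
    if np.any((arr <= 0.0) | (arr >= 1.0)):
        raise ValueError(f"{name} must lie strictly inside (0, 1)")
    return arr


def cross_entropy(y_hat, y) -> float | np.ndarray:
    """-[y log p + (1-y) log(1-p)] for Bernoulli labels y in {0, 1}."""
    p = _check_prob(y_hat)
    y = np.asarray(y, dtype=np.float64)
    out = -(y * np.log(p) + (1.0 - y) * np.log1p(-p))
    return float(out) if out.ndim == 0 else out


def rdrop_kl(y1, y2) -> float | np.ndarray:
    """Symmetric Bernoulli KL: (D(p1||p2) + D(p2||p1)) / 2.

    Zero iff the two dropout passes agree; this is the R-drop penalty.
    """
    p1 = _check_prob(y1, "y1")
    p2 = _check_prob(y2, "y2")

    def kl(a, b):
        return a * (np.log(a) - np.log(b)) + (1 - a) * (np.log1p(-a) - np.log1p(-b))

    out = 0.5 * (kl(p1, p2) + kl(p2, p1))
    return float(out) if out.ndim == 0 else out


def total_loss(y1, y2, y, alpha: float) -> LossBreakdown:
    """Averaged two-pass cross-entropy plus alpha times the symmetric KL."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    cross = 0.5 * (np.mean(cross_entropy(y1, y)) + np.mean(cross_entropy(y2, y)))
    kl = float(np.mean(rdrop_kl(y1, y2)))
    return LossBreakdown(cross=float(cross), kl=kl, alpha=float(alpha))


def binarize(prob, threshold: float = 0.5) -> np.ndarray | int:
    """Hard label: 1 iff prob >= threshold (the boundary counts positive)."""
    arr = np.asarray(prob, dtype=np.float64)
    if np.any((arr < 0.0) | (arr > 1.0)):
        raise ValueError("probabilities must lie in [0, 1]")
    out = (arr >= threshold).astype(np.int64)
    return int(out) if out.ndim == 0 else out


# -- autograd (logit-space) versions ---------------------------------------


def cross_entropy_from_logits(logits: Tensor, y: np.ndarray) -> Tensor:
    """Mean BCE from logits: softplus(z) - y z, numerically stable."""
    y = np.asarray(y, dtype=np.float64)
    return (logits.softplus() - logits * Tensor(y)).mean()


def rdrop_kl_from_logits(z1: Tensor, z2: Tensor) -> Tensor:
    """Mean symmetric Bernoulli KL between sigmoid(z1) and sigmoid(z2)."""
    p1, p2 = z1.sigmoid(), z2.sigmoid()
    # log p = -softplus(-z); log(1-p) = -softplus(z)
    lp1, lp2 = -(-z1).softplus(), -(-z2).softplus()
    lq1, lq2 = -z1.softplus(), -z2.softplus()
    kl12 = p1 * (lp1 - lp2) + (1.0 - p1) * (lq1 - lq2)
    kl21 = p2 * (lp2 - lp1) + (1.0 - p2) * (lq2 - lq1)
    return ((kl12 + kl21) * 0.5).mean()


def total_loss_from_logits(z1: Tensor, z2: Tensor, y: np.ndarray,
                           alpha: float) -> tuple[Tensor, LossBreakdown]:
    """Training objective on two stochastic passes; returns the graph node
    and a detached breakdown for tracing."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    cross = (cross_entropy_from_logits(z1, y) + cross_entropy_from_logits(z2, y)) * 0.5
    kl = rdrop_kl_from_logits(z1, z2)
    loss = cross + alpha * kl if alpha > 0 else cross
    return loss, LossBreakdown(cross=cross.item(), kl=kl.item(), alpha=alpha)
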