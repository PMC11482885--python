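"""Pre-training objectives: decoupled contrastive loss, masked-language-modeling
loss, and their weighted combination.

**Decoupled contrastive loss (DCL).**  Given a batch of N positive pairs with
unit-norm projections ``z_i^1, z_i^2``, each anchor contributes

    L_i = log Σ_{k≠i, l'∈{1,2}} exp(⟨z_i^l, z_k^{l'}⟩ / τ)  −  w_i ⟨z_i^1, z_i^2⟩ / τ

i.e. the positive term is *decoupled* from the negative log-sum-exp (both
views of sample i are excluded from the denominator).  The loss is averaged
over all 2N anchors.  ``τ`` defaults to 0.1; ``w_i`` down-weights harder
augmentation sources (0.8 for orthology-derived pairs, 1.0 otherwise).

**MLM.**  15% of positions are corrupted by zeroing their nucleotide channels;
the loss is the mean cross-entropy between the true one-hot base and the
predicted base distribution, over the masked set only.

**Joint objective.**  ``L_total = (1 − α)·L_CL + α·L_MLM`` with α = 0.95,
compensating the smaller numerical scale of the MLM term.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np

from ._autodiff import Tensor
from .transcripts import SixTrackEncoding

__all__ = [
    "DCLConfig",
    "MLMBatch",
    "LossReport",
    "dcl_loss",
    "dcl_loss_tensor",
    "mlm_loss",
    "mlm_loss_from_logits",
    "apply_mlm_corruption",
    "combined_loss",
]

logger = logging.getLogger(__name__)

_PROB_FLOOR = 1e-12


@dataclasses.dataclass(frozen=True)
class DCLConfig:
    temperature: float = 0.1
    source_weights: tuple[tuple[str, float], ...] = (
        ("splicing", 1.0),
        ("orthology", 0.8),
        ("naive_orthology", 1.0),
        ("masking", 1.0),
    )

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        for name, w in self.source_weights:
            if not 0.0 < w <= 1.0:
                raise ValueError(f"weight for {name!r} must be in (0, 1]")

    def weight(self, source: str) -> float:
        return dict(self.source_weights).get(source, 1.0)


@dataclasses.dataclass
class MLMBatch:
    """Targets and predictions at masked positions of one sequence batch."""

    targets: np.ndarray  # (L, 4) one-hot true bases
    predictions: np.ndarray  # (L, 4) probability vectors
    masked: np.ndarray  # indices into L


@dataclasses.dataclass(frozen=True)
class LossReport:
    l_cl: float
    l_mlm: float
    alpha: float

    @property
    def l_total(self) -> float:
        return (1.0 - self.alpha) * self.l_cl + self.alpha * self.l_mlm


# ---------------------------------------------------------------------------
# DCL
# ---------------------------------------------------------------------------

def dcl_loss_tensor(Z1: Tensor, Z2: Tensor, weights: np.ndarray, temperature: float) -> Tensor:
    """Differentiable DCL loss over all 2N anchors (rows assumed unit-norm)."""
    N = Z1.shape[0]
    S = Tensor.concatenate([Z1, Z2], axis=0)  # (2N, d)
    sims = (S @ S.swapaxes(0, 1)) * (1.0 / temperature)  # (2N, 2N)
    idx = np.arange(2 * N)
    partner = (idx + N) % (2 * N)
    excl = np.full((2 * N, 2 * N), 0.0)
    excl[idx, idx] = -1e30
    excl[idx, partner] = -1e30
    neg = (sims + Tensor(excl)).logsumexp(axis=1)  # (2N,)
    pos = (Z1 * Z2).sum(axis=1) * (1.0 / temperature)  # (N,)
    w = np.asarray(weights, float)
    # each pair contributes its (identical) positive term from both anchors,
    # so the 2N-anchor average of the positive part is the pair-wise mean
    weighted_pos = pos * Tensor(w)
    return neg.mean() - weighted_pos.mean()


def dcl_loss(
    Z1: np.ndarray,
    Z2: np.ndarray,
    weights: np.ndarray | None = None,
    cfg: DCLConfig = DCLConfig(),
) -> float:
    """DCL loss of a batch of unit-norm projection pairs (validating wrapper)."""
    Z1 = np.asarray(Z1, float)
    Z2 = np.asarray(Z2, float)
    if Z1.shape != Z2.shape or Z1.ndim != 2:
        raise ValueError("Z1 and Z2 must be matching N x d matrices")
    N = Z1.shape[0]
    if N < 2:
        raise ValueError("DCL needs at least 2 pairs (no negatives otherwise)")
    for Z in (Z1, Z2):
        norms = np.linalg.norm(Z, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("projection rows must be unit-norm")
    if weights is None:
        weights = np.ones(N)
    out = dcl_loss_tensor(Tensor(Z1), Tensor(Z2), np.asarray(weights, float), cfg.temperature)
    val = float(out.data)
    if not np.isfinite(val):
        raise FloatingPointError("DCL loss is non-finite")
    return val


# ---------------------------------------------------------------------------
# MLM
# ---------------------------------------------------------------------------

def mlm_loss(batch: MLMBatch) -> float:
    """Mean cross-entropy over the masked set; unmasked positions contribute 0."""
    masked = np.asarray(batch.masked, dtype=int)
    if masked.size == 0:
        raise ValueError("masked set is empty")
    P = np.asarray(batch.predictions, float)[masked]
    X = np.asarray(batch.targets, float)[masked]
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("prediction rows must sum to 1")
    true_p = (P * X).sum(axis=1)
    if np.any(true_p < _PROB_FLOOR):
        logger.warning("clamping %d near-zero probabilities in MLM loss", int((true_p < _PROB_FLOOR).sum()))
    true_p = np.maximum(true_p, _PROB_FLOOR)
    return float(-np.mean(np.log(true_p)))


def mlm_loss_from_logits(logits: Tensor, targets: np.ndarray, masked_flat: np.ndarray) -> Tensor:
    """Differentiable MLM loss from per-position logits.

    ``logits`` is (B, L, 4); ``targets`` one-hot (B, L, 4); ``masked_flat`` is
    a boolean (B, L) array marking the corrupted positions.
    """
    if not masked_flat.any():
        raise ValueError("masked set is empty")
    log_probs = logits - logits.logsumexp(axis=2, keepdims=True)
    per_pos = (log_probs * Tensor(targets)).sum(axis=2)  # (B, L)
    m = masked_flat.astype(float)
    return -(per_pos * Tensor(m)).sum() * (1.0 / m.sum())


def apply_mlm_corruption(
    enc: SixTrackEncoding, fraction: float = 0.15, rng: np.random.Generator | None = None
) -> tuple[SixTrackEncoding, np.ndarray]:
    """Zero nucleotide channels at ⌊fraction·L_valid⌋ positions; returns (X̃, ℳ).

    Structural channels are untouched and the input is not modified in place.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    rng = rng if rng is not None else np.random.default_rng()
    out = enc.copy()
    valid = np.flatnonzero(enc.mask)
    k = int(fraction * valid.size)
    masked = np.sort(rng.choice(valid, size=k, replace=False)) if k else np.array([], dtype=int)
    out.matrix[masked, :4] = 0.0
    return out, masked


# ---------------------------------------------------------------------------
# combination
# ---------------------------------------------------------------------------

def combined_loss(l_cl: float, l_mlm: float, alpha: float = 0.95) -> LossReport:
    """α-weighted total loss ``(1 − α)·L_CL + α·L_MLM``."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    return LossReport(l_cl=float(l_cl), l_mlm=float(l_mlm), alpha=alpha)
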