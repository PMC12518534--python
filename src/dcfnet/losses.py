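"""Hybrid segmentation objective: weighted Dice + cross-entropy.

``Loss = lam * L_CE + (1 - lam) * L_Dice`` with lam in [0, 1]
(0.4 for the multi-class CT/MRI profiles, 0.5 for binary dermoscopy).
Both terms operate on softmax probability maps (B, C, H, W) against
integer label masks (B, H, W).
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, as_tensor
from .config import ConfigError

__all__ = ["softmax_probs", "one_hot", "cross_entropy_loss", "dice_loss",
           "hybrid_loss", "soft_dice_per_class"]

_DICE_EPS = 1e-6


def softmax_probs(logits) -> Tensor:
    """Class softmax of logits (B, C, H, W) along the channel axis."""
    t = logits if isinstance(logits, Tensor) else as_tensor(logits)
    return ad.softmax(t.transpose(0, 2, 3, 1), axis=-1).transpose(0, 3, 1, 2)


def one_hot(labels: np.ndarray, num_classes: int) -> np.ndarray:
    """(B, H, W) int labels -> (B, C, H, W) one-hot float array."""
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= num_classes:
        raise ValueError(f"labels outside [0, {num_classes - 1}]")
    eye = np.eye(num_classes, dtype=np.float64)
    return np.moveaxis(eye[labels], -1, 1)


def _prep(P, L):
    Pt = P if isinstance(P, Tensor) else as_tensor(np.asarray(P, dtype=np.float64))
    if Pt.ndim == 3:
        Pt = Pt.reshape(1, *Pt.shape)
    L = np.asarray(L)
    if L.ndim == 2:
        L = L[None]
    C = Pt.shape[1]
    if L.shape != (Pt.shape[0], Pt.shape[2], Pt.shape[3]):
        raise ValueError(f"probability map {Pt.shape} and label mask {L.shape} disagree")
    return Pt, one_hot(L, C)


def cross_entropy_loss(P, L) -> Tensor:
    """-(1/N) sum_i sum_c L_ic log P_ic over all pixels (clamped log)."""
    Pt, oh = _prep(P, L)
    n_pix = oh.shape[0] * oh.shape[2] * oh.shape[3]
    ll = ad.clipped_log(Pt) * oh
    return -ll.sum() * (1.0 / n_pix)


def soft_dice_per_class(P, L) -> Tensor:
    """Per-class soft Dice coefficients 2*sum(P*L)/(sum P + sum L), shape (C,).

    The denominator carries a 1e-6 guard so an absent class with zero
    predicted mass yields Dice 0 for that class rather than 0/0."""
    Pt, oh = _prep(P, L)
    inter = (Pt * oh).sum(axis=(0, 2, 3))
    denom = Pt.sum(axis=(0, 2, 3)) + oh.sum(axis=(0, 2, 3))
    return (2.0 * inter) / (denom + _DICE_EPS)


def dice_loss(P, L) -> Tensor:
    """1 - mean over classes of the soft Dice coefficient."""
    return 1.0 - soft_dice_per_class(P, L).mean()


def hybrid_loss(P, L, lam: float) -> Tensor:
    """lam * cross-entropy + (1 - lam) * Dice loss."""
    if not (0.0 <= lam <= 1.0):
        raise ConfigError(f"lam must lie in [0, 1], got {lam}")
    return lam * cross_entropy_loss(P, L) + (1.0 - lam) * dice_loss(P, L)
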