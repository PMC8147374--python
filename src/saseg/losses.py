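"""Combo training loss: weighted binary cross-entropy plus soft Dice.

``L = w1 * L_BCE + w2 * L_Dice`` with both weights defaulting to 1.  BCE
handles per-pixel calibration while the Dice term counteracts the heavy
foreground/background imbalance of a thin bone in a large field of view.

Probabilities are clipped to ``[eps, 1-eps]`` before the logs.  The Dice
term carries a smoothing constant ``s=1`` in numerator and denominator,
which defines the empty-target/empty-prediction case (otherwise 0/0) and
keeps training stable on all-background slices.

All three losses accept either autograd tensors (differentiable path
used in training) or plain NumPy arrays (returning floats).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor

__all__ = ["LossConfig", "bce_loss", "dice_loss", "combo_loss"]

_DICE_SMOOTH = 1.0


@dataclass(frozen=True)
class LossConfig:
    """Trade-off weights for the combo loss and the log-clipping constant."""

    w_bce: float = 1.0
    w_dice: float = 1.0
    eps: float = 1e-7

    def __post_init__(self):
        if self.w_bce < 0 or self.w_dice < 0:
            raise ValueError("loss weights must be >= 0")
        if self.w_bce == 0 and self.w_dice == 0:
            raise ValueError("at least one loss weight must be positive")
        if not 0 < self.eps <= 1e-3:
            raise ValueError("eps must lie in (0, 1e-3]")


def _prep(yhat, y) -> tuple[Tensor, np.ndarray, bool]:
    tensor_in = isinstance(yhat, Tensor)
    t = yhat if tensor_in else Tensor(np.asarray(yhat, dtype=np.float32))
    target = np.asarray(y.data if isinstance(y, Tensor) else y, dtype=np.float32)
    if t.shape != target.shape:
        raise ValueError(f"shape mismatch: prediction {t.shape} vs target {target.shape}")
    return t, target, tensor_in


def _ret(out: Tensor, tensor_in: bool):
    return out if tensor_in else float(out.data)


def bce_loss(yhat, y, eps: float = 1e-7):
    """Mean binary cross-entropy ``-(1/N) sum[y log p + (1-y) log(1-p)]``."""
    p, t, tensor_in = _prep(yhat, y)
    p = p.clip(eps, 1.0 - eps)
    loss = -((Tensor(t) * p.log() + Tensor(1.0 - t) * (1.0 - p).log()).mean())
    return _ret(loss, tensor_in)


def dice_loss(yhat, y, smooth: float = _DICE_SMOOTH):
    """Soft Dice loss ``1 - (2 sum(y p) + s) / (sum y + sum p + s)``."""
    p, t, tensor_in = _prep(yhat, y)
    inter = (p * Tensor(t)).sum()
    denom = p.sum() + float(t.sum())
    loss = 1.0 - (2.0 * inter + smooth) / (denom + smooth)
    return _ret(loss, tensor_in)


def combo_loss(yhat, y, cfg: LossConfig | None = None):
    """Weighted sum ``w1 * BCE + w2 * Dice`` (differentiable in ``yhat``)."""
    cfg = cfg or LossConfig()
    p, t, tensor_in = _prep(yhat, y)
    loss = Tensor(np.zeros(()))
    if cfg.w_bce:
        loss = loss + cfg.w_bce * bce_loss(p, t, eps=cfg.eps)
    if cfg.w_dice:
        loss = loss + cfg.w_dice * dice_loss(p, t)
    return _ret(loss, tensor_in)
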