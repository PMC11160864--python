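"""Supervised focal-dice loss and the combined multi-task objective.

The student (and teacher, during pretraining) is supervised by a
focal-dice loss: a hardness-weighted cross-entropy term
``-mean((1-p_true)^gamma * log(p_true))`` plus a soft-dice overlap term
``1 - (2*sum(p_fg*g)+eps) / (sum(p_fg)+sum(g)+eps)``, summed with unit
weights.  The full training objective combines it with the four
distillation terms:

    total = seg + beta * (UFD + IFD) + lambda * (UPD + IPD)

with defaults beta=0.9, lambda=0.1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, astensor, softmax
from .config import LossWeights

_LOG_EPS = 1e-8


@dataclass
class LossBreakdown:
    """Per-component record of one multi-task loss evaluation."""

    seg: Tensor | float
    ufd: Tensor | float
    ifd: Tensor | float
    upd: Tensor | float
    ipd: Tensor | float
    total: Tensor | float

    def as_floats(self) -> dict[str, float]:
        return {k: float(getattr(self, k))
                for k in ("seg", "ufd", "ifd", "upd", "ipd", "total")}


def focal_dice_loss(logits, mask, weights: LossWeights | None = None) -> Tensor:
    """Focal cross-entropy plus soft dice against a binary mask.

    `logits` is (K,H,W) or (N,K,H,W) with K >= 2 classes (class 0 =
    background, foreground probability = 1 - p[0]); `mask` is the
    matching (H,W) or (N,H,W) array over {0,1}.
    """
    weights = weights or LossWeights()
    t = astensor(logits)
    m = np.asarray(mask)
    if t.ndim == 3:
        t = t.reshape((1,) + t.shape)
    if m.ndim == 2:
        m = m[None]
    if t.shape[-2:] != m.shape[-2:] or t.shape[0] != m.shape[0]:
        raise ValueError(f"logits {t.shape} and mask {m.shape} are not aligned")
    uniq = np.unique(m)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError(f"mask must be binary, found values {uniq}")
    m = m.astype(np.int64)

    p = softmax(t, axis=1)
    k = t.shape[1]
    onehot = np.eye(k)[m].transpose(0, 3, 1, 2)  # (N,K,H,W)
    p_true = (p * onehot).sum(axis=1)
    focal = -(((1.0 - p_true) ** weights.focal_gamma)
              * (p_true + _LOG_EPS).log()).mean()

    p_fg = 1.0 - p[:, 0]
    g = m.astype(float)
    inter = (p_fg * g).sum()
    denom = p_fg.sum() + g.sum()
    dice = 1.0 - (2.0 * inter + weights.dice_eps) / (denom + weights.dice_eps)
    return focal + dice


def hlfd_loss(seg, ufd, ifd, upd, ipd,
              weights: LossWeights | None = None) -> LossBreakdown:
    """Combine the five components into the multi-task objective.

    Any component may be a float or a live Tensor (gradients flow
    through Tensors); the breakdown's ``total`` is
    seg + beta*(ufd+ifd) + lambda*(upd+ipd).
    """
    weights = weights or LossWeights()
    comps = {"seg": seg, "ufd": ufd, "ifd": ifd, "upd": upd, "ipd": ipd}
    for name, c in comps.items():
        val = c.data if isinstance(c, Tensor) else c
        if not np.all(np.isfinite(val)):
            raise FloatingPointError(f"non-finite loss component: {name}")
    total = seg + weights.beta * (ufd + ifd) + weights.lambda_ * (upd + ipd)
    return LossBreakdown(seg=seg, ufd=ufd, ifd=ifd, upd=upd, ipd=ipd, total=total)
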