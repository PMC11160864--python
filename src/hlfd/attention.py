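"""Feature-level layer-selective feedback distillation (FLFD).

Knowledge is moved *backwards* through the hierarchy: the teacher's
unified middle representation supervises the student's early layer
(UFD), and the teacher's late representation supervises every student
middle layer (IFD).  Supervision is expressed through spatial attention
maps: a feature stack is collapsed across channels by summing powered
absolute activations, flattened, and L2-normalized, so only *where* a
layer attends is compared, never raw magnitudes.

Per term the loss is the norm of the difference of two unit attention
vectors, so each UFD/IFD term lies in [0, 2] and vanishes exactly when
the two layers attend to the same locations.  IFD *sums* its per-layer
terms.  Inputs may be raw arrays, :class:`~hlfd.autodiff.Tensor`,
:class:`~hlfd.networks.FeatureMap` or :class:`UnifiedMid`; batched
(N,C,H,W) inputs return the mean per-sample loss.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .autodiff import Tensor, astensor, concatenate, maximum_scalar, resize2d, tabs
from .config import DistillConfig
from .networks import FeatureMap, RepBundle

_DEFAULT = DistillConfig()

# tiny constant inside sqrt so the gradient of an L2 norm is finite at 0;
# far below every comparison tolerance used here
_SQRT_TINY = 1e-16


@dataclass
class AttentionVector:
    """Flattened, L2-normalized spatial attention map."""

    values: Tensor
    source_shape: tuple[int, int]


@dataclass
class UnifiedMid:
    """Channel-concatenation of middle features at the smallest mid size."""

    values: Tensor
    layer_id: str = "mid_unified"

    @property
    def spatial(self) -> tuple[int, int]:
        return self.values.shape[-2:]


def _vals(f) -> Tensor:
    if isinstance(f, (FeatureMap, UnifiedMid)):
        return f.values
    t = astensor(f)
    if not np.all(np.isfinite(t.data)):
        raise ValueError("non-finite values in feature map")
    return t


def attention_map(f, exponent: float = 1.0) -> Tensor:
    """Channel-aggregated spatial importance: sum_c |f[c]|**exponent.

    Output shape (H,W) for a (C,H,W) input, (N,H,W) for batched input;
    entries are nonnegative by construction.
    """
    t = _vals(f)
    if t.ndim not in (3, 4):
        raise ValueError("attention_map expects (C,H,W) or (N,C,H,W)")
    a = tabs(t)
    if exponent != 1.0:
        a = a ** exponent
    return a.sum(axis=-3)


def unify_mids(mids: Sequence, mode: str = "bilinear") -> UnifiedMid:
    """Concatenate middle features at the smallest middle spatial size.

    Larger maps are resampled down to (min H, min W) over the list, then
    all are stacked along the channel axis in input order.
    """
    if len(mids) == 0:
        raise ValueError("unify_mids requires a non-empty list")
    ts = [_vals(m) for m in mids]
    target = (min(t.shape[-2] for t in ts), min(t.shape[-1] for t in ts))
    ts = [resize2d(t, target, mode=mode) for t in ts]
    if len(ts) == 1:
        return UnifiedMid(ts[0])
    return UnifiedMid(concatenate(ts, axis=-3))


def normalized_attention(f, target_shape: tuple[int, int] | None = None,
                         exponent: float = 1.0, eps: float = 1e-8,
                         mode: str = "bilinear") -> AttentionVector:
    """Resample features to `target_shape`, aggregate channels, unit-normalize.

    The feature stack is resampled first and the attention map computed
    on the resampled stack.  The flattened map is divided by
    max(L2 norm, eps); an all-zero map therefore returns the zero
    vector instead of NaN.  Batched input gives one unit vector per
    sample, shape (N, H*W).
    """
    t = _vals(f)
    if t.ndim not in (3, 4):
        raise ValueError("normalized_attention expects (C,H,W) or (N,C,H,W)")
    if target_shape is not None:
        th, tw = int(target_shape[0]), int(target_shape[1])
        if th < 1 or tw < 1:
            raise ValueError("target_shape must be positive")
        t = resize2d(t, (th, tw), mode=mode)
    a = attention_map(t, exponent)
    shape = a.shape[-2:]
    if a.ndim == 3:
        v = a.reshape((a.shape[0], -1))
    else:
        v = a.flatten()
    norm = ((v * v).sum(axis=-1, keepdims=True) + _SQRT_TINY) ** 0.5
    v = v / maximum_scalar(norm, eps)
    return AttentionVector(values=v, source_shape=shape)


def _diff_norm(vs: Tensor, vt: Tensor, kind: str) -> Tensor:
    d = vs - vt
    if kind == "l1":
        per = tabs(d).sum(axis=-1)
    else:
        per = ((d * d).sum(axis=-1) + _SQRT_TINY) ** 0.5
    return per.mean() if per.ndim == 1 else per


def ufd_loss(z_early_s, z_mid_t, cfg: DistillConfig | None = None) -> Tensor:
    """Unified feature distillation: early student vs unified teacher mid.

    The student early features are rescaled to the unified teacher
    middle map's spatial size; the loss is the norm of the difference of
    the two normalized attention vectors.
    """
    cfg = cfg or _DEFAULT
    target = _vals(z_mid_t).shape[-2:]
    vs = normalized_attention(z_early_s, target, cfg.attention_exponent,
                              cfg.eps, cfg.interp_mode).values
    vt = normalized_attention(z_mid_t, None, cfg.attention_exponent,
                              cfg.eps, cfg.interp_mode).values
    return _diff_norm(vs, vt, cfg.diff_norm)


def ifd_loss(mids_s: Sequence, z_late_t, cfg: DistillConfig | None = None) -> Tensor:
    """Individual feature distillation: each student mid vs teacher late.

    Every student middle tap is rescaled to the teacher late spatial
    size and compared to the (single) teacher late attention vector;
    per-layer terms are summed.
    """
    if len(mids_s) == 0:
        raise ValueError("ifd_loss requires a non-empty list of student mids")
    cfg = cfg or _DEFAULT
    target = _vals(z_late_t).shape[-2:]
    vt = normalized_attention(z_late_t, None, cfg.attention_exponent,
                              cfg.eps, cfg.interp_mode).values
    total = None
    for m in mids_s:
        vs = normalized_attention(m, target, cfg.attention_exponent,
                                  cfg.eps, cfg.interp_mode).values
        term = _diff_norm(vs, vt, cfg.diff_norm)
        total = term if total is None else total + term
    return total


def flfd_terms(reps_s: RepBundle, reps_t: RepBundle,
               cfg: DistillConfig | None = None) -> tuple[Tensor, Tensor]:
    """The two feature-level terms (UFD, IFD) for a bundle pair."""
    cfg = cfg or _DEFAULT
    unified = unify_mids(reps_t.mids, mode=cfg.interp_mode)
    return (ufd_loss(reps_s.early, unified, cfg),
            ifd_loss(reps_s.mids, reps_t.late, cfg))


def flfd_loss(reps_s: RepBundle, reps_t: RepBundle,
              cfg: DistillConfig | None = None) -> Tensor:
    """Total feature-level loss: UFD + IFD."""
    ufd, ifd = flfd_terms(reps_s, reps_t, cfg)
    return ufd + ifd
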