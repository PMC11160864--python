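"""Pixel-level layer-selective feedback distillation (PLFD).

Where the feature-level losses compare attention geometry, the
pixel-level losses compare per-pixel class *distributions*.  The frozen
teacher's decoder emits predictive maps at every decoder tap; the
unified middle predictive map supervises the student's early auxiliary
map (UPD) and the terminal predictive map supervises each student
middle auxiliary map (IPD), via a per-pixel KL divergence averaged over
pixels.

Two deliberate asymmetries with the feature level are pinned by tests:
teacher middle maps are *averaged* (probability simplices cannot be
channel-concatenated), and IPD *averages* its per-layer terms where IFD
sums.  The KL is taken with the student distribution first,
KL(student || teacher); the classic direction is available through
``DistillConfig.kl_direction``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .autodiff import Tensor, astensor, resize2d, softmax
from .config import DistillConfig
from .networks import NestedUNetTeacher, PredBundle, RepBundle, StudentAux

_DEFAULT = DistillConfig()


def _pmap(p) -> Tensor:
    t = astensor(p)
    if t.ndim not in (3, 4):
        raise ValueError("probability map must be (K,H,W) or (N,K,H,W)")
    return t


def validate_probmap(p, tol: float = 1e-6) -> None:
    """Check the ProbMap invariants: entries in [0,1], pixel sums 1."""
    t = _pmap(p)
    if t.data.min() < -tol or t.data.max() > 1 + tol:
        raise ValueError("probability map entries must lie in [0, 1]")
    sums = t.data.sum(axis=-3)
    if np.abs(sums - 1.0).max() > tol:
        raise ValueError("per-pixel class probabilities must sum to 1")


def teacher_pred_maps(teacher: NestedUNetTeacher, reps: RepBundle,
                      cfg: DistillConfig | None = None) -> PredBundle:
    """Decode the teacher taps into per-pixel class distributions.

    The bundle's encoder features (whose ``late`` member is the decoder
    input, the rest enter through skip connections) are passed through
    the frozen teacher decoder; every head's logit map is converted to a
    probability map by a per-pixel softmax.
    """
    cfg = cfg or _DEFAULT
    if not teacher.spec.deep_supervision:
        raise ValueError("teacher lacks deep-supervision heads")
    logits = teacher.decode(reps)
    t = 1.0 / cfg.temperature

    def sm(x: Tensor) -> Tensor:
        return softmax(x * t if cfg.temperature != 1.0 else x, axis=-3)

    return PredBundle(early=sm(logits.early),
                      mids=[sm(m) for m in logits.mids],
                      late=sm(logits.late))


def unify_teacher_mid_probs(mids: Sequence, target_shape: tuple[int, int],
                            mode: str = "bilinear") -> Tensor:
    """Average the teacher middle predictive maps at a common size.

    Each map is resampled to ``target_shape`` and the maps are averaged
    across layers; the result is renormalized per pixel so it remains a
    valid class distribution.
    """
    if len(mids) == 0:
        raise ValueError("unify_teacher_mid_probs requires a non-empty list")
    ts = [_pmap(m) for m in mids]
    ks = {t.shape[-3] for t in ts}
    if len(ks) != 1:
        raise ValueError(f"class-count mismatch across mid maps: {sorted(ks)}")
    acc = None
    for t in ts:
        r = resize2d(t, tuple(target_shape), mode=mode)
        acc = r if acc is None else acc + r
    avg = acc * (1.0 / len(ts))
    return avg / avg.sum(axis=-3, keepdims=True)


def kl_pixelwise(p_student, p_teacher, eps: float = 1e-8) -> Tensor:
    """Mean over pixels of sum_k p_s[k] * log((p_s[k]+eps)/(p_t[k]+eps)).

    Natural logarithm; ``eps`` smooths both arguments so one-hot maps
    are handled.  Nonnegative up to eps-smoothing error.
    """
    ps, pt = _pmap(p_student), _pmap(p_teacher)
    if ps.shape != pt.shape:
        raise ValueError(f"shape mismatch: {ps.shape} vs {pt.shape}")
    per_pixel = (ps * ((ps + eps).log() - (pt + eps).log())).sum(axis=-3)
    return per_pixel.mean()


def _student_probs(logits, target_shape, cfg: DistillConfig) -> Tensor:
    t = astensor(logits)
    t = resize2d(t, tuple(target_shape), mode=cfg.interp_mode)
    if cfg.temperature != 1.0:
        t = t * (1.0 / cfg.temperature)
    return softmax(t, axis=-3)


def _kl(ps: Tensor, pt, cfg: DistillConfig) -> Tensor:
    if cfg.kl_direction == "classic":
        return kl_pixelwise(pt, ps, cfg.kl_eps)
    return kl_pixelwise(ps, pt, cfg.kl_eps)


def upd_loss(student_early_logits, teacher_mid_probs,
             cfg: DistillConfig | None = None) -> Tensor:
    """Unified pixel distillation: student early map vs unified teacher mid.

    The student's early auxiliary logits are rescaled to the teacher
    map's resolution, softmaxed, and compared by pixel-wise KL.
    """
    cfg = cfg or _DEFAULT
    pt = _pmap(teacher_mid_probs)
    ps = _student_probs(student_early_logits, pt.shape[-2:], cfg)
    return _kl(ps, pt, cfg)


def ipd_loss(student_mid_logits: Sequence, p_late_t,
             cfg: DistillConfig | None = None) -> Tensor:
    """Individual pixel distillation: mean KL of each student mid map
    against the teacher's terminal predictive map (1/N averaging)."""
    if len(student_mid_logits) == 0:
        raise ValueError("ipd_loss requires a non-empty list of student mids")
    cfg = cfg or _DEFAULT
    pt = _pmap(p_late_t)
    total = None
    for logits in student_mid_logits:
        ps = _student_probs(logits, pt.shape[-2:], cfg)
        term = _kl(ps, pt, cfg)
        total = term if total is None else total + term
    return total * (1.0 / len(student_mid_logits))


def plfd_terms(student_aux: StudentAux, teacher_bundle: PredBundle,
               cfg: DistillConfig | None = None) -> tuple[Tensor, Tensor]:
    """The two pixel-level terms (UPD, IPD) for a student/teacher pair.

    The teacher middle maps are unified at the smallest middle-map
    resolution (mirroring the feature-level rule) before UPD.
    """
    cfg = cfg or _DEFAULT
    mids = teacher_bundle.mids
    target = (min(m.shape[-2] for m in mids), min(m.shape[-1] for m in mids))
    unified = unify_teacher_mid_probs(mids, target, mode=cfg.interp_mode)
    upd = upd_loss(student_aux.early, unified, cfg)
    ipd = ipd_loss(student_aux.mids, teacher_bundle.late, cfg)
    return upd, ipd


def plfd_loss(student_aux: StudentAux, teacher_bundle: PredBundle,
              cfg: DistillConfig | None = None) -> Tensor:
    """Total pixel-level loss: UPD + IPD."""
    upd, ipd = plfd_terms(student_aux, teacher_bundle, cfg)
    return upd + ipd
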