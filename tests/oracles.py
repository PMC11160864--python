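"""Independent literal-formula oracles used by the test suite.

Everything here is written straight from the method's defining formulas
with plain numpy loops, deliberately sharing no code with the library's
autodiff path.  Resampling uses the standard half-pixel-centre separable
linear interpolation rule, spelled out longhand.
"""

from __future__ import annotations

import numpy as np


def resample_1d_weights(n_in: int, n_out: int) -> np.ndarray:
    w = np.zeros((n_out, n_in))
    for i in range(n_out):
        src = (i + 0.5) * n_in / n_out - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        j0 = int(np.floor(src))
        j1 = min(j0 + 1, n_in - 1)
        t = src - j0
        w[i, j0] += 1.0 - t
        w[i, j1] += t
    return w


def resample2d(arr: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    """Bilinear resampling of the trailing two axes, longhand."""
    h, w = arr.shape[-2:]
    oh, ow = out_hw
    if (h, w) == (oh, ow):
        return arr.copy()
    wh = resample_1d_weights(h, oh)
    ww = resample_1d_weights(w, ow)
    flat = arr.reshape(-1, h, w)
    out = np.empty((flat.shape[0], oh, ow))
    for c in range(flat.shape[0]):
        out[c] = wh @ flat[c] @ ww.T
    return out.reshape(arr.shape[:-2] + (oh, ow))


def attention_vector(f: np.ndarray, target_hw: tuple[int, int] | None = None,
                     exponent: float = 1.0, eps: float = 1e-8) -> np.ndarray:
    """vec(A(z)) / ||vec(A(z))||_2 with A = channel sum of |.|^p after rescale."""
    f = np.asarray(f, dtype=float)
    if target_hw is not None:
        f = resample2d(f, target_hw)
    c, h, w = f.shape
    amap = np.zeros((h, w))
    for ci in range(c):
        for yi in range(h):
            for xi in range(w):
                amap[yi, xi] += abs(f[ci, yi, xi]) ** exponent
    v = amap.reshape(-1)
    return v / max(np.sqrt((v ** 2).sum()), eps)


def ufd(z_early_s: np.ndarray, z_mid_t: np.ndarray,
        exponent: float = 1.0, eps: float = 1e-8) -> float:
    """Unified feature distillation term, straight from its definition."""
    target = z_mid_t.shape[-2:]
    vs = attention_vector(z_early_s, target, exponent, eps)
    vt = attention_vector(z_mid_t, None, exponent, eps)
    return float(np.sqrt(((vs - vt) ** 2).sum()))


def ifd(mids_s: list[np.ndarray], z_late_t: np.ndarray,
        exponent: float = 1.0, eps: float = 1e-8) -> float:
    """Sum over student middle layers of the late-vs-mid attention term."""
    target = z_late_t.shape[-2:]
    vt = attention_vector(z_late_t, None, exponent, eps)
    total = 0.0
    for m in mids_s:
        vs = attention_vector(m, target, exponent, eps)
        total += float(np.sqrt(((vs - vt) ** 2).sum()))
    return total


def softmax_np(logits: np.ndarray, axis: int = 0) -> np.ndarray:
    e = np.exp(logits - logits.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def kl_pixelwise(p_s: np.ndarray, p_t: np.ndarray, eps: float = 1e-8) -> float:
    """Mean over pixels of sum_k p_s log((p_s+eps)/(p_t+eps)), looped."""
    k, h, w = p_s.shape
    total = 0.0
    for yi in range(h):
        for xi in range(w):
            for ki in range(k):
                total += p_s[ki, yi, xi] * np.log(
                    (p_s[ki, yi, xi] + eps) / (p_t[ki, yi, xi] + eps))
    return total / (h * w)


def upd(student_early_logits: np.ndarray, teacher_mid_probs: np.ndarray,
        eps: float = 1e-8) -> float:
    """KL(softmax(rescaled student logits) || unified teacher mid map)."""
    target = teacher_mid_probs.shape[-2:]
    ps = softmax_np(resample2d(student_early_logits, target), axis=0)
    return kl_pixelwise(ps, teacher_mid_probs, eps)


def ipd(student_mid_logits: list[np.ndarray], p_late_t: np.ndarray,
        eps: float = 1e-8) -> float:
    """Mean over layers (1/N) of the per-layer student-vs-terminal KL."""
    target = p_late_t.shape[-2:]
    total = 0.0
    for logits in student_mid_logits:
        ps = softmax_np(resample2d(logits, target), axis=0)
        total += kl_pixelwise(ps, p_late_t, eps)
    return total / len(student_mid_logits)


def focal_dice(logits: np.ndarray, mask: np.ndarray, gamma: float = 2.0,
               dice_eps: float = 1.0, log_eps: float = 1e-8) -> float:
    """Focal cross-entropy + soft dice, looped over pixels."""
    k, h, w = logits.shape
    p = softmax_np(logits, axis=0)
    focal = 0.0
    inter = 0.0
    sum_fg = 0.0
    sum_g = 0.0
    for yi in range(h):
        for xi in range(w):
            pt = p[int(mask[yi, xi]), yi, xi]
            focal += -((1.0 - pt) ** gamma) * np.log(pt + log_eps)
            fg = 1.0 - p[0, yi, xi]
            inter += fg * mask[yi, xi]
            sum_fg += fg
            sum_g += mask[yi, xi]
    focal /= h * w
    dice = 1.0 - (2.0 * inter + dice_eps) / (sum_fg + sum_g + dice_eps)
    return focal + dice


def random_simplex_map(rng: np.random.Generator, k: int, h: int, w: int
                       ) -> np.ndarray:
    """Random per-pixel class distributions (Dirichlet draws)."""
    p = rng.dirichlet(np.ones(k), size=(h, w))
    return np.moveaxis(p, -1, 0)
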