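"""Synthetic CT-like phantoms with tumor masks.

Each phantom is a 2-D slice in pseudo-Hounsfield units: a soft-tissue
background with smooth texture, one elliptical organ (kidney- or
liver-typical HU band), and 0-3 hypodense tumor blobs with irregular
radial-noise boundaries, all degraded by additive Gaussian noise.
Standard radiological windowing maps HU to [0,1] network inputs.

The generator is the data source for every test and training run in
this package; it emulates the intensity structure that makes tumor
segmentation in windowed CT non-trivial (low lesion contrast, texture,
noise) without claiming anatomical realism.  Difficulty levels trade
tumor/organ contrast against noise:

========== ================== ==============
difficulty contrast delta (HU) noise sd (HU)
========== ================== ==============
easy       85                 4
medium     70                 6
hard       55                 8
========== ================== ==============

Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

# organ-typical soft-tissue HU bands and radiological display windows
ORGAN_HU = {"kidney": (20.0, 45.0), "liver": (40.0, 60.0)}
WINDOWS = {"kidney": (-200.0, 300.0), "liver": (-40.0, 160.0)}

DIFFICULTY = {
    "easy": {"contrast": 85.0, "noise_sd": 4.0},
    "medium": {"contrast": 70.0, "noise_sd": 6.0},
    "hard": {"contrast": 55.0, "noise_sd": 8.0},
}

# 16-bit PNG encoding of HU values: u16 = (HU + offset) * scale
_PNG_OFFSET = 1024.0
_PNG_SCALE = 16.0


@dataclass
class WindowSpec:
    """A Hounsfield display window [lo, hi]."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"window requires lo < hi, got ({self.lo}, {self.hi})")


@dataclass
class PhantomSample:
    """One synthetic slice: HU image, binary tumor mask, metadata."""

    image: np.ndarray
    mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        self.mask = np.asarray(self.mask)
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask shapes differ")
        if not np.all(np.isin(np.unique(self.mask), (0, 1))):
            raise ValueError("mask must be binary")
        self.mask = self.mask.astype(np.uint8)


def hu_window(image, w: WindowSpec) -> np.ndarray:
    """Clamp HU values to [w.lo, w.hi] and map affinely to [0, 1]."""
    if not isinstance(w, WindowSpec):
        w = WindowSpec(*w)
    img = np.asarray(image, dtype=float)
    return (np.clip(img, w.lo, w.hi) - w.lo) / (w.hi - w.lo)


def window_for(organ: str) -> WindowSpec:
    return WindowSpec(*WINDOWS[organ])


def _smooth_noise(rng: np.random.Generator, size: int, sigma: float,
                  amplitude: float) -> np.ndarray:
    """Low-frequency texture: blurred white noise rescaled to unit sd."""
    n = ndimage.gaussian_filter(rng.normal(size=(size, size)), sigma)
    sd = n.std()
    if sd < 1e-12:
        return np.zeros((size, size))
    return amplitude * n / sd


def _blob_mask(rng: np.random.Generator, size: int, cy: float, cx: float,
               r0: float) -> np.ndarray:
    """Irregular blob: radius modulated by a low-order Fourier series."""
    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - cy, xx - cx
    theta = np.arctan2(dy, dx)
    r = np.hypot(dy, dx)
    bound = np.full((size, size), r0)
    for k in range(2, 6):
        amp = rng.normal(0.0, 0.35 / k)
        phase = rng.uniform(0.0, 2 * np.pi)
        bound = bound + r0 * amp * np.cos(k * theta + phase)
    return r <= np.maximum(bound, 1.0)


def generate_phantoms(n: int, size: int = 64, organ: str = "kidney",
                      difficulty: str = "medium", seed: int = 0,
                      tumor_count_probs: tuple = (0.2, 0.4, 0.25, 0.15),
                      ) -> list[PhantomSample]:
    """Generate `n` deterministic phantom slices.

    Each sample has one organ ellipse in its organ-typical HU band,
    0-3 hypodense tumor blobs (contrast set by `difficulty`) clipped to
    the organ interior, background texture, and pixel noise.  With the
    default tumor-count distribution 80% of samples carry at least one
    tumor.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if size < 16:
        raise ValueError("size must be >= 16")
    if organ not in ORGAN_HU:
        raise ValueError(f"unknown organ {organ!r}")
    if difficulty not in DIFFICULTY:
        raise ValueError(f"unknown difficulty {difficulty!r}")
    diff = DIFFICULTY[difficulty]
    rng = np.random.default_rng(seed)
    lo_hu, hi_hu = ORGAN_HU[organ]
    samples = []
    yy, xx = np.mgrid[0:size, 0:size]
    for idx in range(n):
        # background: darker soft tissue with coarse texture
        img = rng.uniform(-100.0, -40.0) + _smooth_noise(rng, size, size / 8, 15.0)
        # organ ellipse
        cy = size / 2 + rng.uniform(-0.08, 0.08) * size
        cx = size / 2 + rng.uniform(-0.08, 0.08) * size
        a = rng.uniform(0.22, 0.34) * size
        b = rng.uniform(0.22, 0.34) * size
        phi = rng.uniform(0.0, np.pi)
        dy, dx = yy - cy, xx - cx
        u = dx * np.cos(phi) + dy * np.sin(phi)
        v = -dx * np.sin(phi) + dy * np.cos(phi)
        organ_mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        organ_hu = rng.uniform(lo_hu, hi_hu)
        img[organ_mask] = organ_hu + _smooth_noise(rng, size, size / 10, 5.0)[organ_mask]
        # tumors: hypodense blobs inside the organ
        mask = np.zeros((size, size), dtype=bool)
        k = rng.choice(4, p=np.asarray(tumor_count_probs) / np.sum(tumor_count_probs))
        for _ in range(k):
            for _attempt in range(50):
                t_ang = rng.uniform(0.0, 2 * np.pi)
                t_rad = rng.uniform(0.0, 0.6)
                tcy = cy + t_rad * b * np.sin(t_ang)
                tcx = cx + t_rad * a * np.cos(t_ang)
                if organ_mask[int(round(tcy)) % size, int(round(tcx)) % size]:
                    break
            r0 = rng.uniform(0.08, 0.15) * size
            blob = _blob_mask(rng, size, tcy, tcx, r0) & organ_mask
            tumor_hu = organ_hu - diff["contrast"] + rng.normal(0.0, 3.0)
            img[blob] = tumor_hu + _smooth_noise(rng, size, size / 12, 3.0)[blob]
            mask |= blob
        img = img + rng.normal(0.0, diff["noise_sd"], (size, size))
        samples.append(PhantomSample(
            image=img, mask=mask.astype(np.uint8),
            meta={"organ": organ, "difficulty": difficulty,
                  "seed": int(seed), "index": idx,
                  "organ_ellipse": {"center": [float(cy), float(cx)],
                                    "axes": [float(a), float(b)],
                                    "angle": float(phi)}}))
    return samples


def augment(sample: PhantomSample, seed: int) -> PhantomSample:
    """Random 90-degree rotation plus flips, identical on image and mask.

    Restricted to the 8 symmetries of the square so masks stay exactly
    binary (no resampling).
    """
    rng = np.random.default_rng(seed)
    k = int(rng.integers(0, 4))
    do_flip = bool(rng.integers(0, 2))
    img, msk = np.rot90(sample.image, k), np.rot90(sample.mask, k)
    if do_flip:
        img, msk = np.flip(img, axis=1), np.flip(msk, axis=1)
    return PhantomSample(image=img.copy(), mask=msk.copy(),
                         meta={**sample.meta, "augmented": True})


def augment_arrays(image: np.ndarray, mask: np.ndarray,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Array-level rotation/flip used inside training loops; consumes two draws."""
    k = int(rng.integers(0, 4))
    do_flip = bool(rng.integers(0, 2))
    img = np.rot90(image, k, axes=(-2, -1))
    msk = np.rot90(mask, k, axes=(-2, -1))
    if do_flip:
        img, msk = np.flip(img, axis=-1), np.flip(msk, axis=-1)
    return np.ascontiguousarray(img), np.ascontiguousarray(msk)


# ---------------------------------------------------------------------------
# dataset I/O: 16-bit PNG images + 8-bit PNG masks + JSON manifest
# ---------------------------------------------------------------------------

def save_dataset(samples: list[PhantomSample], outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, s in enumerate(samples):
        img16 = np.clip((s.image + _PNG_OFFSET) * _PNG_SCALE, 0, 65535)
        img16 = np.round(img16).astype(np.uint16)
        img_name, mask_name = f"sample_{i:05d}.png", f"sample_{i:05d}_mask.png"
        Image.fromarray(img16).save(outdir / img_name)
        Image.fromarray((s.mask * 255).astype(np.uint8)).save(outdir / mask_name)
        entries.append({"id": i, "image": img_name, "mask": mask_name,
                        "meta": s.meta})
    manifest = {"encoding": {"offset": _PNG_OFFSET, "scale": _PNG_SCALE},
                "samples": entries}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def load_dataset(path) -> list[PhantomSample]:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    off = manifest["encoding"]["offset"]
    sc = manifest["encoding"]["scale"]
    samples = []
    for e in manifest["samples"]:
        img16 = np.asarray(Image.open(path / e["image"]), dtype=float)
        img = img16 / sc - off
        msk = (np.asarray(Image.open(path / e["mask"])) > 127).astype(np.uint8)
        samples.append(PhantomSample(image=img, mask=msk, meta=e.get("meta", {})))
    return samples


def save_nifti_stack(samples: list[PhantomSample], image_path, mask_path) -> None:
    """Optional volume-shaped export of a phantom list as NIfTI pairs."""
    import nibabel as nib

    img = np.stack([s.image for s in samples], axis=-1)
    msk = np.stack([s.mask for s in samples], axis=-1).astype(np.uint8)
    nib.save(nib.Nifti1Image(img.astype(np.float32), np.eye(4)), str(image_path))
    nib.save(nib.Nifti1Image(msk, np.eye(4)), str(mask_path))


def load_nifti_stack(image_path, mask_path, meta: dict | None = None
                     ) -> list[PhantomSample]:
    """Read a NIfTI image/mask volume pair as a list of 2-D slices."""
    import nibabel as nib

    img = np.asanyarray(nib.load(str(image_path)).dataobj).astype(float)
    msk = (np.asanyarray(nib.load(str(mask_path)).dataobj) > 0).astype(np.uint8)
    if img.shape != msk.shape:
        raise ValueError("image and mask volumes have different shapes")
    return [PhantomSample(image=img[..., i], mask=msk[..., i],
                          meta=dict(meta or {}, index=i))
            for i in range(img.shape[-1])]
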