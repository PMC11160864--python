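"""Reference teacher/student segmentation networks with named taps.

The distillation framework needs two things from any network pair:

* encoder activations tapped at an *early* stage, N *middle* stages and
  a *late* (terminal) stage, packaged as a :class:`RepBundle`;
* from the teacher, a decoder with deep supervision emitting a
  class-logit map per decoder tap (:class:`PredBundle`); from the
  student, a final full-resolution logit map plus detachable auxiliary
  1x1 class-projection heads on the early and middle taps.

The built-in networks are miniature analogues of the architectures used
for full-scale CT work: the teacher is a nested-skip encoder-decoder
(UNet++-style) with deep supervision, the student a residual-block
encoder with a light upsampling head.  Both are sized for tens of
thousands of parameters so they train in minutes on one CPU; channel
widths are configurable if something bigger is wanted.

Encoder layout: stage 0 keeps full resolution ("early"), every later
stage halves it, so with stage channels ``[8, 16, 32, 64]`` a 64x64
input yields middle taps at 32x32 and 16x16 and a late tap at 8x8.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concatenate, conv2d, relu, resize2d
from .config import ConfigError


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class FeatureMap:
    """An encoder activation: values (C,H,W) or batched (N,C,H,W), plus a tag."""

    values: Tensor
    layer_id: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.values, Tensor):
            self.values = Tensor(np.asarray(self.values))
        if self.values.ndim not in (3, 4):
            raise ValueError("FeatureMap values must be (C,H,W) or (N,C,H,W)")
        if not np.all(np.isfinite(self.values.data)):
            raise ValueError(f"non-finite values in feature map {self.layer_id!r}")

    @property
    def spatial(self) -> tuple[int, int]:
        return self.values.shape[-2:]

    @property
    def channels(self) -> int:
        return self.values.shape[-3]


@dataclass
class RepBundle:
    """Early / middle / late encoder taps, spatially non-increasing."""

    early: FeatureMap
    mids: list[FeatureMap]
    late: FeatureMap

    def __post_init__(self) -> None:
        if len(self.mids) < 1:
            raise ValueError("RepBundle needs at least one middle tap")
        sizes = [self.early.spatial] + [m.spatial for m in self.mids] + [self.late.spatial]
        for a, b in zip(sizes, sizes[1:]):
            if b[0] > a[0] or b[1] > a[1]:
                raise ValueError(f"spatial size must be non-increasing, got {sizes}")

    @property
    def n_mid(self) -> int:
        return len(self.mids)


@dataclass
class PredBundle:
    """Per-tap class maps (logits or probabilities), all with equal class count."""

    early: Tensor
    mids: list[Tensor]
    late: Tensor

    def __post_init__(self) -> None:
        ks = {t.shape[-3] for t in [self.early, *self.mids, self.late]}
        if len(ks) != 1:
            raise ValueError(f"inconsistent class counts in PredBundle: {ks}")

    @property
    def num_classes(self) -> int:
        return self.late.shape[-3]


@dataclass
class StudentAux:
    """Auxiliary class-logit maps from the student's early and middle taps."""

    early: Tensor
    mids: list[Tensor]


@dataclass
class NetworkSpec:
    role: str = "teacher"
    stage_channels: list[int] = field(default_factory=lambda: [8, 16, 32, 64])
    num_classes: int = 2
    in_channels: int = 1
    deep_supervision: bool = True
    tap_plan: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.role not in ("teacher", "student"):
            raise ConfigError(f"role must be teacher or student, got {self.role!r}")
        if any(c < 1 for c in self.stage_channels):
            raise ConfigError("stage_channels must be positive")
        if len(self.stage_channels) < 3:
            raise ConfigError(
                "need at least 3 stages (1 early + N>=1 mid + 1 late), "
                f"got {len(self.stage_channels)}")
        if self.num_classes < 2:
            raise ConfigError("num_classes must be >= 2")
        if self.role == "teacher" and not self.deep_supervision:
            raise ConfigError("teacher spec requires deep_supervision=true")
        if not self.tap_plan:
            n = self.n_mid
            self.tap_plan = ["early"] + [f"mid{j + 1}" for j in range(n)] + ["late"]
        if len(self.tap_plan) != len(self.stage_channels):
            raise ConfigError(
                f"tap_plan names {len(self.tap_plan)} stages but "
                f"stage_channels has {len(self.stage_channels)}")
        if len(set(self.tap_plan)) != len(self.tap_plan):
            raise ConfigError("tap_plan stage names must be distinct")

    @property
    def n_mid(self) -> int:
        return len(self.stage_channels) - 2


def default_teacher_spec(**kw) -> NetworkSpec:
    return NetworkSpec(role="teacher", stage_channels=[8, 16, 32, 64], **kw)


def default_student_spec(**kw) -> NetworkSpec:
    return NetworkSpec(role="student", stage_channels=[8, 16, 24, 32],
                       deep_supervision=False, **kw)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Conv:
    """3x3 (or 1x1) convolution with He-normal init."""

    def __init__(self, rng: np.random.Generator, cin: int, cout: int,
                 k: int = 3, stride: int = 1):
        std = np.sqrt(2.0 / (cin * k * k))
        self.w = Tensor(rng.normal(0.0, std, (cout, cin, k, k)), requires_grad=True)
        self.b = Tensor(np.zeros(cout), requires_grad=True)
        self.stride = stride
        self.padding = k // 2

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, padding=self.padding)

    @property
    def params(self) -> list[Tensor]:
        return [self.w, self.b]


class ResBlock:
    """Two 3x3 convolutions with a projection shortcut; first conv may stride."""

    def __init__(self, rng, cin: int, cout: int, stride: int = 1):
        self.conv1 = Conv(rng, cin, cout, 3, stride)
        self.conv2 = Conv(rng, cout, cout, 3, 1)
        self.proj = Conv(rng, cin, cout, 1, stride) if (cin != cout or stride != 1) else None

    def __call__(self, x: Tensor) -> Tensor:
        h = relu(self.conv1(x))
        h = self.conv2(h)
        s = self.proj(x) if self.proj is not None else x
        return relu(h + s)

    @property
    def params(self) -> list[Tensor]:
        ps = self.conv1.params + self.conv2.params
        if self.proj is not None:
            ps += self.proj.params
        return ps


class _Network:
    spec: NetworkSpec
    seed: int

    def parameters(self) -> list[Tensor]:
        raise NotImplementedError

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    @property
    def frozen(self) -> bool:
        return all(not p.requires_grad for p in self.parameters())


class NestedUNetTeacher(_Network):
    """Nested-skip encoder-decoder with one deep-supervision head per level.

    Encoder nodes X[i][0] supply the representation taps.  Decoder node
    X[i][j] (j >= 1) convolves the concatenation of all previous nodes
    at level i with the upsampled node X[i+1][j-1].  Predictive-map
    heads sit on the bottleneck and on the deepest decoding path, one
    per resolution: bottleneck -> early map, intermediate path nodes ->
    middle maps, full-resolution node -> late (final) map.
    """

    def __init__(self, spec: NetworkSpec, seed: int):
        if spec.role != "teacher":
            raise ConfigError("NestedUNetTeacher requires a teacher spec")
        spec.__post_init__()
        self.spec = spec
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        ch = spec.stage_channels
        L = len(ch)
        self.enc = [Conv(rng, spec.in_channels if i == 0 else ch[i - 1], ch[i],
                         3, 1 if i == 0 else 2) for i in range(L)]
        # decoder grid: dec[(i, j)] maps concat(j*ch[i] + ch[i+1]) -> ch[i]
        self.dec: dict[tuple[int, int], Conv] = {}
        for i in range(L - 1):
            for j in range(1, L - i):
                cin = j * ch[i] + ch[i + 1]
                self.dec[(i, j)] = Conv(rng, cin, ch[i], 3, 1)
        # heads: bottleneck + deepest path nodes X[i][L-1-i]
        self.head_early = Conv(rng, ch[L - 1], spec.num_classes, 1)
        self.head_mids = [Conv(rng, ch[i], spec.num_classes, 1)
                          for i in range(L - 2, 0, -1)]
        self.head_late = Conv(rng, ch[0], spec.num_classes, 1)

    def parameters(self) -> list[Tensor]:
        ps: list[Tensor] = []
        for c in self.enc:
            ps += c.params
        for key in sorted(self.dec):
            ps += self.dec[key].params
        ps += self.head_early.params
        for h in self.head_mids:
            ps += h.params
        ps += self.head_late.params
        return ps

    def encode(self, x: Tensor) -> RepBundle:
        if x.ndim == 3:
            x = x.reshape((1,) + x.shape)
        feats = []
        h = x
        for conv in self.enc:
            h = relu(conv(h))
            feats.append(h)
        names = self.spec.tap_plan
        return RepBundle(
            early=FeatureMap(feats[0], names[0]),
            mids=[FeatureMap(f, n) for f, n in zip(feats[1:-1], names[1:-1])],
            late=FeatureMap(feats[-1], names[-1]))

    def decode(self, reps: RepBundle) -> PredBundle:
        """Run the nested decoder off the encoder taps; returns logit maps."""
        L = len(self.spec.stage_channels)
        X: dict[tuple[int, int], Tensor] = {}
        taps = [reps.early.values] + [m.values for m in reps.mids] + [reps.late.values]
        for i in range(L):
            X[(i, 0)] = taps[i]
        for j in range(1, L):
            for i in range(L - j):
                below = resize2d(X[(i + 1, j - 1)], X[(i, 0)].shape[-2:])
                cat = concatenate([X[(i, k)] for k in range(j)] + [below], axis=1)
                X[(i, j)] = relu(self.dec[(i, j)](cat))
        early = self.head_early(X[(L - 1, 0)])
        mids = [h(X[(i, L - 1 - i)]) for h, i in
                zip(self.head_mids, range(L - 2, 0, -1))]
        late = self.head_late(X[(0, L - 1)])
        return PredBundle(early=early, mids=mids, late=late)

    def forward(self, x: Tensor) -> tuple[RepBundle, PredBundle]:
        reps = self.encode(x)
        return reps, self.decode(reps)


class ResNetStudent(_Network):
    """Residual-block encoder with a light bilinear-upsampling head.

    The full-resolution logit map comes from the decoder head; the
    auxiliary 1x1 class-projection heads on the early and middle taps
    exist only to receive pixel-level distillation and are dropped by
    :meth:`export_for_inference`.
    """

    def __init__(self, spec: NetworkSpec, seed: int, with_aux: bool = True):
        if spec.role != "student":
            raise ConfigError("ResNetStudent requires a student spec")
        spec.__post_init__()
        self.spec = spec
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        ch = spec.stage_channels
        L = len(ch)
        self.stem = Conv(rng, spec.in_channels, ch[0], 3, 1)
        self.blocks = [ResBlock(rng, ch[i - 1], ch[i], stride=2) for i in range(1, L)]
        # upsampling head: one conv per doubling, late channels -> ch[0]
        self.up = [Conv(rng, ch[L - 1 - i], ch[L - 2 - i], 3, 1) for i in range(L - 1)]
        self.head = Conv(rng, ch[0], spec.num_classes, 1)
        self.with_aux = with_aux
        if with_aux:
            self.aux_early = Conv(rng, ch[0], spec.num_classes, 1)
            self.aux_mids = [Conv(rng, ch[i], spec.num_classes, 1)
                             for i in range(1, L - 1)]
        else:
            # consume the same rng draws so core weights match an aux build
            Conv(rng, ch[0], spec.num_classes, 1)
            for i in range(1, L - 1):
                Conv(rng, ch[i], spec.num_classes, 1)
            self.aux_early = None
            self.aux_mids = []

    def parameters(self) -> list[Tensor]:
        ps = self.stem.params[:]
        for b in self.blocks:
            ps += b.params
        for c in self.up:
            ps += c.params
        ps += self.head.params
        if self.with_aux and self.aux_early is not None:
            ps += self.aux_early.params
            for c in self.aux_mids:
                ps += c.params
        return ps

    def core_parameters(self) -> list[Tensor]:
        """Parameters kept at inference (everything but auxiliary heads)."""
        ps = self.stem.params[:]
        for b in self.blocks:
            ps += b.params
        for c in self.up:
            ps += c.params
        ps += self.head.params
        return ps

    def encode(self, x: Tensor) -> RepBundle:
        if x.ndim == 3:
            x = x.reshape((1,) + x.shape)
        h = relu(self.stem(x))
        feats = [h]
        for b in self.blocks:
            h = b(h)
            feats.append(h)
        names = self.spec.tap_plan
        return RepBundle(
            early=FeatureMap(feats[0], names[0]),
            mids=[FeatureMap(f, n) for f, n in zip(feats[1:-1], names[1:-1])],
            late=FeatureMap(feats[-1], names[-1]))

    def segment(self, reps: RepBundle) -> Tensor:
        h = reps.late.values
        # climb back up: late -> ... -> early resolution
        sizes = [m.spatial for m in reversed(reps.mids)] + [reps.early.spatial]
        for conv, size in zip(self.up, sizes):
            h = relu(conv(resize2d(h, size)))
        return self.head(h)

    def forward(self, x: Tensor) -> tuple[RepBundle, Tensor, StudentAux | None]:
        reps = self.encode(x)
        logits = self.segment(reps)
        aux = None
        if self.with_aux and self.aux_early is not None:
            aux = StudentAux(
                early=self.aux_early(reps.early.values),
                mids=[c(m.values) for c, m in zip(self.aux_mids, reps.mids)])
        return reps, logits, aux

    def export_for_inference(self) -> "ResNetStudent":
        """Copy of the student without auxiliary heads; final output unchanged."""
        out = ResNetStudent(self.spec, self.seed, with_aux=False)
        for p_dst, p_src in zip(out.core_parameters(), self.core_parameters()):
            p_dst.data = p_src.data.copy()
            p_dst.requires_grad = False
        return out


# ---------------------------------------------------------------------------
# builders, freezing, checkpoints
# ---------------------------------------------------------------------------

def build_teacher(spec: NetworkSpec, seed: int) -> NestedUNetTeacher:
    if spec.role != "teacher":
        raise ConfigError("build_teacher needs spec.role == 'teacher'")
    return NestedUNetTeacher(spec, seed)


def build_student(spec: NetworkSpec, seed: int) -> ResNetStudent:
    if spec.role != "student":
        raise ConfigError("build_student needs spec.role == 'student'")
    return ResNetStudent(spec, seed)


def freeze(net: _Network) -> _Network:
    """Detach every parameter from the gradient tape (teacher contract)."""
    for p in net.parameters():
        p.requires_grad = False
    return net


def save_checkpoint(net: _Network, path) -> None:
    """Serialized parameters (.npz) plus a JSON sidecar with spec and seed."""
    path = Path(path)
    arrays = {f"p{i}": p.data for i, p in enumerate(net.parameters())}
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {
        "role": net.spec.role,
        "stage_channels": net.spec.stage_channels,
        "num_classes": net.spec.num_classes,
        "in_channels": net.spec.in_channels,
        "deep_supervision": net.spec.deep_supervision,
        "tap_plan": net.spec.tap_plan,
        "seed": net.seed,
        "with_aux": getattr(net, "with_aux", None),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path) -> _Network:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    spec = NetworkSpec(
        role=meta["role"], stage_channels=meta["stage_channels"],
        num_classes=meta["num_classes"], in_channels=meta["in_channels"],
        deep_supervision=meta["deep_supervision"], tap_plan=meta["tap_plan"])
    if meta["role"] == "teacher":
        net: _Network = NestedUNetTeacher(spec, meta["seed"])
    else:
        net = ResNetStudent(spec, meta["seed"], with_aux=bool(meta["with_aux"]))
    data = np.load(path.with_suffix(".npz"))
    params = net.parameters()
    if len(params) != len(data.files):
        raise ConfigError("checkpoint does not match rebuilt architecture")
    for i, p in enumerate(params):
        p.data = data[f"p{i}"]
    return net
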