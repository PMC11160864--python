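"""Structured configuration for the distillation framework.

Two dataclasses travel through the whole library: ``DistillConfig``
(hyper-parameters of the attention and pixel distillation losses) and
``LossWeights`` (the multi-task mixing weights plus the supervised-loss
internals).  ``TrainConfig`` in :mod:`hlfd.pipeline` embeds both.  YAML
round-tripping is provided for the CLI.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import yaml


class ConfigError(ValueError):
    """Raised for invalid network or training configuration."""


@dataclass
class DistillConfig:
    """Hyper-parameters of the feature- and pixel-level distillation losses.

    attention_exponent
        Exponent applied to absolute activations before channel
        aggregation (1 = sum of absolute values, 2 = energy).
    interp_mode
        Spatial resampling mode for feature maps and probability maps
        ("bilinear" or "nearest").
    eps
        Guard in the attention-vector L2 normalization denominator.
    diff_norm
        Norm of the attention-vector difference ("l2" or "l1").
    kl_direction
        "as_written": KL(student || teacher); "classic": KL(teacher || student).
    kl_eps
        Smoothing added inside the KL log ratio.
    temperature
        Softmax temperature applied to all predictive-map logits.
    """

    attention_exponent: float = 1.0
    interp_mode: str = "bilinear"
    eps: float = 1e-8
    diff_norm: str = "l2"
    kl_direction: str = "as_written"
    kl_eps: float = 1e-8
    temperature: float = 1.0

    def __post_init__(self) -> None:
        if self.attention_exponent <= 0:
            raise ConfigError("attention_exponent must be positive")
        if self.interp_mode not in ("bilinear", "nearest"):
            raise ConfigError(f"unknown interp_mode {self.interp_mode!r}")
        if self.diff_norm not in ("l2", "l1"):
            raise ConfigError(f"unknown diff_norm {self.diff_norm!r}")
        if self.kl_direction not in ("as_written", "classic"):
            raise ConfigError(f"unknown kl_direction {self.kl_direction!r}")
        if self.temperature <= 0:
            raise ConfigError("temperature must be positive")


@dataclass
class LossWeights:
    """Multi-task loss weights: total = seg + beta*(UFD+IFD) + lambda*(UPD+IPD).

    ``beta`` weighs the feature-level pair, ``lambda_`` the pixel-level
    pair.  ``focal_gamma`` and ``dice_eps`` parameterize the supervised
    focal-dice loss.
    """

    beta: float = 0.9
    lambda_: float = 0.1
    focal_gamma: float = 2.0
    dice_eps: float = 1.0

    def __post_init__(self) -> None:
        if self.beta < 0 or self.lambda_ < 0:
            raise ConfigError("beta and lambda must be nonnegative")
        if self.focal_gamma < 0:
            raise ConfigError("focal_gamma must be nonnegative")
        if self.dice_eps <= 0:
            raise ConfigError("dice_eps must be positive")


def to_yaml(obj, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(obj), fh, sort_keys=False)


def dataclass_from_mapping(cls, mapping: dict):
    """Build a dataclass, rejecting unknown keys (typo protection)."""
    valid = set(cls.__dataclass_fields__)
    unknown = set(mapping) - valid
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**mapping)
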