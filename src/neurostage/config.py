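"""Run configuration: one object bundling every stage's parameters.

A single global seed deterministically derives each stage's sub-seed (by
stage-name hashing, see :func:`neurostage.data.derive_seed`), so adding a
stage never perturbs another stage's randomness.  Configs round-trip through
YAML; the CLI overlays flag values on top of a loaded file.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .backbone import BackboneSpec, HeadTrainConfig
from .data import AugmentationConfig, BalancePlan, PhantomConfig
from .enhancement import ContrastParams, DehazeParams
from .exceptions import ConfigError

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    """Everything a training/evaluation run needs, resolved and seeded."""

    data_root: str | None = None
    out_dir: str = "runs/latest"
    seed: int = 0
    backbone: BackboneSpec = field(default_factory=BackboneSpec)
    heads: int = 4
    use_gsa: bool = True
    enhance: bool = True
    dehaze: DehazeParams = field(default_factory=DehazeParams)
    contrast: ContrastParams = field(default_factory=ContrastParams)
    train: HeadTrainConfig = field(default_factory=HeadTrainConfig)
    balance: BalancePlan = field(default_factory=BalancePlan)
    augment: AugmentationConfig = field(default_factory=AugmentationConfig)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    split_fractions: tuple = (0.8, 0.2)
    n_hidden: int = 100
    elm_activation: str = "sigmoid"

    def to_dict(self) -> dict:
        blob = asdict(self)
        blob["backbone"] = asdict(self.backbone)
        return blob


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


_SUBCONFIGS = {
    "backbone": BackboneSpec,
    "dehaze": DehazeParams,
    "contrast": ContrastParams,
    "train": HeadTrainConfig,
    "balance": BalancePlan,
    "augment": AugmentationConfig,
    "phantom": PhantomConfig,
}

_TUPLE_FIELDS = {
    "backbone": ("input_size",),
    "augment": ("rotation_angles", "scale_range", "flips"),
    "phantom": ("image_size", "class_geometry"),
}


def load_config(path) -> RunConfig:
    """Read a YAML file written by :func:`save_config` (or hand-authored with
    the same keys) back into a :class:`RunConfig`."""
    blob = yaml.safe_load(Path(path).read_text())
    if not isinstance(blob, dict):
        raise ConfigError(f"config file {path} does not contain a mapping")
    kwargs: dict = {}
    for key, value in blob.items():
        if key in _SUBCONFIGS:
            if not isinstance(value, dict):
                raise ConfigError(f"config section {key!r} must be a mapping")
            for tf in _TUPLE_FIELDS.get(key, ()):
                if tf in value and value[tf] is not None:
                    value[tf] = tuple(value[tf])
            kwargs[key] = _SUBCONFIGS[key](**value)
        elif key == "split_fractions":
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    try:
        return RunConfig(**kwargs)
    except TypeError as exc:
        raise ConfigError(f"unknown config key: {exc}") from None
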