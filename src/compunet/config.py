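"""YAML configuration loading and validation for the CLI.

Every stage config mirrors its dataclass field-for-field; unknown keys and
missing required keys raise a :class:`ConfigError` naming the field before
any stage runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .loss import LossConfig
from .net import ModelSpec
from .phantom import ArtifactParams, JawArc, Misalignment, PhantomSpec, \
    TrabecularTexture
from .train import TrainConfig


class ConfigError(ValueError):
    pass


_NESTED = {
    "jaw_arc": JawArc, "trabecular_texture": TrabecularTexture,
    "misalignment": Misalignment, "loss": LossConfig,
}
_TUPLE_FIELDS = {"grid_shape", "spacing", "head_radii", "metal_indices",
                 "planes", "layers", "z_extent", "tooth_z_extent",
                 "center_offset_yx", "translation_vox", "rotation_deg"}


def build_dataclass(cls, data: dict, context: str):
    """Construct ``cls`` from a dict, rejecting unknown keys by name."""
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{context}: expected a mapping, got {type(data).__name__}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"{context}: unknown field(s) {sorted(unknown)}")
    kwargs = {}
    for key, val in data.items():
        if key in _NESTED and isinstance(val, dict):
            val = build_dataclass(_NESTED[key], val, f"{context}.{key}")
        elif key in _TUPLE_FIELDS and isinstance(val, list):
            val = tuple(val)
        kwargs[key] = val
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{context}: {exc}") from exc


@dataclass
class RunConfig:
    """Full pipeline configuration (simulate → prep → train → evaluate)."""

    seed: int
    out_dir: str
    n_train: int = 15
    n_test: int = 5
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    artifacts: ArtifactParams = field(default_factory=ArtifactParams)
    train: TrainConfig = field(default_factory=TrainConfig)
    model: ModelSpec = field(default_factory=ModelSpec)
    register: bool = True
    verbosity: int = 1

    REQUIRED = ("seed", "out_dir")

    def validate(self) -> None:
        if self.n_train < 1 or self.n_test < 2:
            raise ConfigError("n_train must be >= 1 and n_test >= 2")
        self.phantom.validate()
        self.artifacts.validate()
        self.train.validate()
        self.model.validate()


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in RunConfig.REQUIRED:
        if key not in raw:
            raise ConfigError(f"missing required field: {key!r}")
    sections = {"phantom": PhantomSpec, "artifacts": ArtifactParams,
                "train": TrainConfig, "model": ModelSpec}
    kwargs = {}
    for key, val in raw.items():
        if key in sections:
            kwargs[key] = build_dataclass(sections[key], val, key)
        else:
            kwargs[key] = val
    names = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(kwargs) - names
    if unknown:
        raise ConfigError(f"run: unknown field(s) {sorted(unknown)}")
    try:
        cfg = RunConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"run: {exc}") from exc
    cfg.validate()
    return cfg


def config_hash(path) -> str:
    with open(path, "rb") as fh:
        return hashlib.sha256(fh.read()).hexdigest()


def manifest(cfg_hash: str, seed: int, extra: dict | None = None) -> dict:
    import numpy
    import scipy
    from . import __version__
    out = {"config_sha256": cfg_hash, "seed": seed,
           "versions": {"compunet": __version__, "numpy": numpy.__version__,
                        "scipy": scipy.__version__}}
    if extra:
        out.update(extra)
    return out
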