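"""YAML configuration loading/validation and run provenance.

A config file has optional ``seed``, ``model``, ``train``, ``loss`` and
``synthetic`` sections; unknown keys are rejected with their field paths, and
section contents are validated by constructing the corresponding runtime
config objects (so e.g. an image size not divisible by the patch size fails
at load time, naming both fields).  An empty file yields the full default
bundle.  Every artifact-producing CLI command writes exactly one JSON run
manifest capturing the config snapshot, master seed, code version and output
paths.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from .encoder import ModelConfig
from .engine import LossConfig, TrainConfig
from .synthetic import SyntheticTaskConfig

__all__ = ["ConfigBundle", "load_config", "dump_config", "RunManifest", "write_manifest"]


def _defaults(cls) -> dict:
    return asdict(cls())


class ConfigBundle(BaseModel):
    """Validated configuration: master seed plus one section per subsystem."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    model: dict = {}
    train: dict = {}
    loss: dict = {}
    synthetic: dict = {}

    @model_validator(mode="after")
    def _validate_sections(self):
        # merge with defaults, reject unknown keys, then let each runtime
        # config's own invariants run
        for name, cls in (("model", ModelConfig), ("train", TrainConfig),
                          ("loss", LossConfig), ("synthetic", SyntheticTaskConfig)):
            section = getattr(self, name)
            defaults = _defaults(cls)
            unknown = set(section) - set(defaults)
            if unknown:
                raise ValueError(f"unknown keys in '{name}': {sorted(unknown)}")
            merged = {**defaults, **section}
            for key in ("window_layers", "betas", "classes", "held_out",
                        "class_intensity_means"):
                if key in merged and isinstance(merged[key], list):
                    merged[key] = tuple(merged[key])
            cls(**merged)  # raises ValueError naming the offending fields
            setattr(self, name, merged)
        return self

    # -- runtime objects -----------------------------------------------------
    def to_model_config(self) -> ModelConfig:
        d = dict(self.model)
        d["window_layers"] = tuple(d["window_layers"])
        return ModelConfig(**d)

    def to_train_config(self) -> TrainConfig:
        d = dict(self.train)
        d["betas"] = tuple(d["betas"])
        d["seed"] = self.seed
        return TrainConfig(**d)

    def to_loss_config(self) -> LossConfig:
        return LossConfig(**self.loss)

    def to_synthetic_config(self) -> SyntheticTaskConfig:
        d = dict(self.synthetic)
        for key in ("classes", "held_out", "class_intensity_means"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        d["seed"] = self.seed
        return SyntheticTaskConfig(**d)


def load_config(path: str | Path | None) -> ConfigBundle:
    """Load and validate a YAML config; None or an empty file give defaults."""
    if path is None:
        return ConfigBundle()
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return ConfigBundle(**data)


def dump_config(bundle: ConfigBundle) -> str:
    """YAML snapshot that round-trips: load(dump(x)) == x."""
    return yaml.safe_dump(
        {"seed": bundle.seed, "model": bundle.model, "train": bundle.train,
         "loss": bundle.loss, "synthetic": bundle.synthetic},
        sort_keys=True,
    )


class RunManifest(BaseModel):
    """Provenance for one artifact-producing run."""

    command: str
    seed: int
    code_version: str
    timestamp: float
    config: dict
    outputs: list[str]


def write_manifest(
    path: str | Path,
    command: str,
    seed: int,
    bundle: ConfigBundle,
    outputs: list[str | Path],
) -> RunManifest:
    from . import __version__

    manifest = RunManifest(
        command=command,
        seed=seed,
        code_version=__version__,
        timestamp=time.time(),
        config={"seed": bundle.seed, "model": bundle.model, "train": bundle.train,
                "loss": bundle.loss, "synthetic": bundle.synthetic},
        outputs=[str(o) for o in outputs],
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(manifest.model_dump_json(indent=2))
    return manifest
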