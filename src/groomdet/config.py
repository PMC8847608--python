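"""Structured config file (YAML, per-stage sections) and run manifests."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .models.arch import ModelConfig
from .models.training import EpochPlan
from .postfilter import FilterParams
from .preprocess import PreprocessConfig
from .synthetic import SceneConfig

SECTIONS = ("preprocess", "model", "train", "filter", "simulate")


class ConfigFileError(ValueError):
    pass


def load_config(path: str | Path | None) -> dict:
    """Load a per-stage config mapping; missing file or None gives all defaults."""
    if path is None:
        return {}
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigFileError(f"{path}: invalid YAML: {exc}") from exc
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ConfigFileError(f"{path}: top level must be a mapping of stage sections")
    unknown = set(data) - set(SECTIONS)
    if unknown:
        raise ConfigFileError(
            f"{path}: unknown section(s) {sorted(unknown)}; expected {list(SECTIONS)}"
        )
    for name, section in data.items():
        if section is not None and not isinstance(section, dict):
            raise ConfigFileError(f"{path}: section {name!r} must be a mapping")
    return {k: (v or {}) for k, v in data.items()}


def _build(cls, section: dict, overrides: dict, stage: str):
    merged = dict(section)
    merged.update({k: v for k, v in overrides.items() if v is not None})
    valid = set(cls.__dataclass_fields__)
    unknown = set(merged) - valid
    if unknown:
        raise ConfigFileError(f"unknown {stage} config key(s): {sorted(unknown)}")
    try:
        return cls(**merged)
    except (TypeError, ValueError) as exc:
        raise ConfigFileError(f"invalid {stage} config: {exc}") from exc


def preprocess_config(cfg: dict, **overrides) -> PreprocessConfig:
    return _build(PreprocessConfig, cfg.get("preprocess", {}), overrides, "preprocess")


def model_config(cfg: dict, **overrides) -> ModelConfig:
    section = dict(cfg.get("model", {}))
    for key in ("conv_widths", "fc_widths", "double_blocks", "lstm_units"):
        if key in section and section[key] is not None:
            section[key] = tuple(section[key])
    return _build(ModelConfig, section, overrides, "model")


def epoch_plan(cfg: dict, **overrides) -> EpochPlan:
    section = {k: v for k, v in cfg.get("train", {}).items()
               if k in EpochPlan.__dataclass_fields__}
    return _build(EpochPlan, section, overrides, "train")


def filter_params(cfg: dict, **overrides) -> FilterParams:
    return _build(FilterParams, cfg.get("filter", {}), overrides, "filter")


def scene_config(cfg: dict, **overrides) -> SceneConfig:
    section = dict(cfg.get("simulate", {}))
    for key in ("body_axes", "facial_osc", "body_osc"):
        if key in section and section[key] is not None:
            section[key] = tuple(section[key])
    return _build(SceneConfig, section, overrides, "simulate")


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with Path(path).open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Everything needed to re-execute one pipeline stage reproducibly."""

    stage: str
    config: dict
    inputs: dict = field(default_factory=dict)
    seed: int | None = None
    version: str = __version__
    started: float = field(default_factory=time.time)
    elapsed_s: float | None = None

    def add_input(self, path: str | Path) -> None:
        path = Path(path)
        self.inputs[str(path)] = sha256_file(path) if path.is_file() else "directory"

    def finish(self) -> None:
        self.elapsed_s = round(time.time() - self.started, 3)

    def write(self, artifact_path: str | Path) -> Path:
        self.finish()
        out = Path(str(artifact_path) + ".manifest.json")
        out.write_text(json.dumps(asdict(self), indent=2, default=str) + "\n")
        return out


def config_dict(obj) -> dict:
    return asdict(obj) if hasattr(obj, "__dataclass_fields__") else dict(obj)
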