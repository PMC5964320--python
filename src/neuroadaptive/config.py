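"""Experiment configuration: strict, schema-versioned YAML/JSON configs."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = ["ExperimentConfig", "load_config", "save_config"]


class HyperparamsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    signal_sd: float = Field(gt=0)
    lengthscales: list[float]
    noise_sd: float = Field(gt=0)


class ExperimentConfig(BaseModel):
    """One closed-loop run: protocol, space/truth inputs, loop and model settings."""

    model_config = ConfigDict(extra="forbid")

    schema_version: int = 1
    protocol: Literal["exp1", "exp2", "exp3"] = "exp1"
    space_file: Optional[str] = None
    truth_file: Optional[str] = None
    burn_in: int = Field(default=5, ge=0)
    iterations: int = Field(gt=0)
    seed: int = 0
    acquisition: Literal["max_predicted", "max_observed"] = "max_predicted"
    tr_seconds: float = Field(default=2.0, gt=0)
    despike_gate: Optional[float] = 3.0
    hyperparams: Optional[HyperparamsConfig] = None
    output_dir: str = "results"

    @model_validator(mode="after")
    def _loop_consistent(self):
        if self.iterations < self.burn_in:
            raise ValueError("iterations must be >= burn_in")
        return self


def load_config(path) -> ExperimentConfig:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    for p in (data.get("space_file"), data.get("truth_file")):
        if p is not None and not (Path(p).exists() or (path.parent / p).exists()):
            raise FileNotFoundError(f"referenced file does not exist: {p}")
    return ExperimentConfig(**data)


def save_config(cfg: ExperimentConfig, path) -> None:
    path = Path(path)
    data = cfg.model_dump()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
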