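"""Run configuration: a single YAML file over immutable printed defaults.

An empty (or absent) file yields the default model and experiment
settings; any field present overrides the corresponding default.
Unknown keys are rejected by name, and all violations found in a file
are reported together.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import ConfigError
from .experiments import EXPERIMENTS
from .params import ModelParams

__all__ = ["RunConfig", "load_config", "save_config"]

_LOG_LEVELS = ("DEBUG", "INFO", "WARNING", "ERROR")


@dataclass(frozen=True)
class RunConfig:
    """Everything a reproducible run needs: model, stimulus, experiment, seeds."""

    model: ModelParams = field(default_factory=ModelParams)
    stimulus: dict = field(default_factory=dict)
    experiment: str = "first_order"
    experiment_args: dict = field(default_factory=dict)
    seeds: list = field(default_factory=lambda: [0])
    output_dir: str = "results"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["model"] = self.model.to_dict()
        return d


def _validate(raw: dict) -> RunConfig:
    errors = []
    known = set(RunConfig.__dataclass_fields__)
    for key in raw:
        if key not in known:
            errors.append(f"unknown key {key!r} (expected one of {sorted(known)})")
    model_raw = raw.get("model", {}) or {}
    model = ModelParams()
    if not isinstance(model_raw, dict):
        errors.append("'model' must be a mapping of parameter names to values")
    else:
        model_known = set(ModelParams.__dataclass_fields__)
        bad = [k for k in model_raw if k not in model_known]
        errors.extend(
            f"unknown model parameter {k!r} (expected one of {sorted(model_known)})"
            for k in bad
        )
        if not bad:
            try:
                model = ModelParams(**model_raw)
            except Exception as e:  # invalid values
                errors.append(f"invalid model parameters: {e}")
    experiment = raw.get("experiment", "first_order")
    if experiment not in EXPERIMENTS:
        errors.append(
            f"unknown experiment {experiment!r} (expected one of {sorted(EXPERIMENTS)})"
        )
    seeds = raw.get("seeds", [0])
    if not isinstance(seeds, list) or not all(isinstance(s, int) for s in seeds):
        errors.append("'seeds' must be a list of integers")
    log_level = str(raw.get("log_level", "INFO")).upper()
    if log_level not in _LOG_LEVELS:
        errors.append(f"log_level must be one of {_LOG_LEVELS}")
    for key in ("stimulus", "experiment_args"):
        if not isinstance(raw.get(key, {}) or {}, dict):
            errors.append(f"{key!r} must be a mapping")
    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(errors))
    return RunConfig(
        model=model,
        stimulus=dict(raw.get("stimulus", {}) or {}),
        experiment=experiment,
        experiment_args=dict(raw.get("experiment_args", {}) or {}),
        seeds=list(seeds),
        output_dir=str(raw.get("output_dir", "results")),
        log_level=log_level,
    )


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    An empty file (or one containing only comments) yields all defaults.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as e:
        raise ConfigError(f"could not parse {path}: {e}") from e
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"top level of {path} must be a mapping")
    return _validate(raw)


def save_config(config: RunConfig, path) -> Path:
    """Write a RunConfig as YAML; load_config(save_config(c)) == c."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    return path
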