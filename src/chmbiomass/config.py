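"""Structured run configuration (YAML) for the CLI pipeline."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .experiment import ExperimentSpec
from .landscape import LandscapeConfig

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Malformed configuration; the message names the offending key."""


@dataclass
class RunConfig:
    landscape: LandscapeConfig
    experiment: ExperimentSpec
    seed: int = 0
    log_level: str = "INFO"

    def with_seed(self, seed: int) -> "RunConfig":
        return RunConfig(
            landscape=dataclasses.replace(self.landscape, seed=seed),
            experiment=dataclasses.replace(self.experiment, seed=seed),
            seed=seed,
            log_level=self.log_level,
        )


def _build(cls, section: dict, where: str):
    known = {f.name for f in dataclasses.fields(cls)}
    bad = set(section) - known
    if bad:
        raise ConfigError(f"unknown key(s) {sorted(bad)} in section '{where}'")
    # YAML gives lists; the dataclasses expect tuples for sequence fields
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in section.items()
    }
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value in section '{where}': {exc}") from exc


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML run configuration.

    Top-level sections: ``landscape``, ``experiment``; optional ``seed`` and
    ``log_level``.  Unknown keys are rejected with a message naming them.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a mapping at the top level")
    known = {"landscape", "experiment", "seed", "log_level"}
    bad = set(raw) - known
    if bad:
        raise ConfigError(f"unknown top-level key(s): {sorted(bad)}")
    seed = int(raw.get("seed", 0))
    land = _build(LandscapeConfig, raw.get("landscape", {}) or {}, "landscape")
    exp = _build(ExperimentSpec, raw.get("experiment", {}) or {}, "experiment")
    cfg = RunConfig(
        landscape=land,
        experiment=exp,
        seed=seed,
        log_level=str(raw.get("log_level", "INFO")),
    )
    if "seed" in raw:
        cfg = cfg.with_seed(seed)
    return cfg
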