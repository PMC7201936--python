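"""Run configuration: YAML scenario/misclassification files.

A config file has up to three top-level blocks::

    scenario:          # every ScenarioSpec field, seed mandatory
      n_variants: 100
      ...
    misclassification: # optional MisclassModel block
      mode: nondifferential
      confusion: [[0.9, 0.1, 0.0], [0.05, 0.9, 0.05], [0.0, 0.1, 0.9]]
    analysis:          # optional thresholds
      p_threshold: 5.0e-8
      r2_threshold: 0.001
      palindrome_window: [0.42, 0.58]

Unknown keys are rejected anywhere in the file, and every command writes
its fully resolved configuration beside its outputs so runs are auditable.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .simulate import ConfigurationError, MisclassModel, ScenarioSpec

__all__ = ["load_config", "load_scenario", "write_resolved_config",
           "DEFAULT_ANALYSIS"]

DEFAULT_ANALYSIS = {
    "p_threshold": 5e-8,
    "r2_threshold": 0.001,
    "palindrome_window": [0.42, 0.58],
    "ci_quantile": 1.96,
}

_TOP_KEYS = {"scenario", "misclassification", "analysis"}


def load_config(path: str) -> dict:
    """Parse and validate a config file into spec objects.

    Returns ``{"scenario": ScenarioSpec, "misclassification":
    MisclassModel | None, "analysis": dict}``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigurationError(f"unknown top-level config keys: "
                                 f"{sorted(unknown)}")
    if "scenario" not in raw:
        raise ConfigurationError("config must contain a 'scenario' block")
    if "seed" not in raw["scenario"]:
        raise ConfigurationError("scenario block must set an explicit seed")
    spec = ScenarioSpec.from_dict(raw["scenario"])
    mis = None
    if raw.get("misclassification") is not None:
        mis = MisclassModel.from_dict(raw["misclassification"])
    analysis = dict(DEFAULT_ANALYSIS)
    extra = raw.get("analysis") or {}
    unknown = set(extra) - set(DEFAULT_ANALYSIS)
    if unknown:
        raise ConfigurationError(f"unknown analysis keys: {sorted(unknown)}")
    analysis.update(extra)
    return {"scenario": spec, "misclassification": mis, "analysis": analysis}


def load_scenario(path: str) -> ScenarioSpec:
    return load_config(path)["scenario"]


def write_resolved_config(config: dict, path: str | Path) -> None:
    """Dump the fully resolved configuration next to a run's outputs."""
    spec = config["scenario"]
    mis = config.get("misclassification")
    out = {"scenario": spec.to_dict(),
           "misclassification": mis.to_dict() if mis is not None else None,
           "analysis": config.get("analysis", dict(DEFAULT_ANALYSIS))}
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)
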