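"""YAML configuration loading for the simulation and case-study pipelines."""

from __future__ import annotations

from dataclasses import dataclass

import yaml

from gcompbias.case_study import CaseStudyEffects
from gcompbias.dgp import DEFAULT_BETA1_GRID
from gcompbias.gcomputation import AdjustmentSet
from gcompbias.simulation_study import (
    DEFAULT_SAMPLE_SIZES,
    StudyGrid,
    default_adjustment_conditions,
)

__all__ = ["ConfigError", "CaseStudyConfig", "load_config", "grid_to_dict",
           "write_config"]

#: Replicate count of the full (non-desk-scale) study design.
FULL_N_REPS = 10_000


class ConfigError(ValueError):
    """A configuration file failed to parse or validate."""


@dataclass(frozen=True)
class CaseStudyConfig:
    """Resolved configuration of a case-study run."""

    n: int = 50_000
    seed: int = 0
    n_bootstrap: int = 200
    include_x3: bool = False
    near_iv_confounding: float = 1.0
    effects: CaseStudyEffects = CaseStudyEffects()

    def __post_init__(self):
        if self.n < 1 or self.n_bootstrap < 2:
            raise ConfigError("n must be >= 1 and n_bootstrap >= 2")


_SIMULATE_KEYS = {
    "scenario", "sample_sizes", "n_reps", "adjustment_conditions",
    "beta1_values", "base_seed",
}
_CASE_KEYS = {"n", "seed", "n_bootstrap", "include_x3",
              "near_iv_confounding", "effects"}


def _build_grid(raw: dict) -> StudyGrid:
    unknown = set(raw) - _SIMULATE_KEYS
    if unknown:
        raise ConfigError(f"unknown simulate config keys: {sorted(unknown)}")
    scenario = raw.get("scenario", "A")
    if scenario not in ("A", "B"):
        raise ConfigError(f"scenario must be 'A' or 'B', got {scenario!r}")
    adj = raw.get("adjustment_conditions")
    try:
        if adj is None or adj == "default":
            conditions = default_adjustment_conditions(scenario)
        else:
            conditions = tuple(AdjustmentSet(tuple(c)) for c in adj)
        return StudyGrid(
            scenario=scenario,
            sample_sizes=tuple(raw.get("sample_sizes", DEFAULT_SAMPLE_SIZES)),
            n_reps=int(raw.get("n_reps", FULL_N_REPS)),
            adjustment_conditions=conditions,
            beta1_values=tuple(raw.get("beta1_values", DEFAULT_BETA1_GRID)),
            base_seed=int(raw.get("base_seed", 20_220_425)),
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def _build_case(raw: dict) -> CaseStudyConfig:
    unknown = set(raw) - _CASE_KEYS
    if unknown:
        raise ConfigError(f"unknown case-study config keys: {sorted(unknown)}")
    effects = raw.get("effects", {})
    if not isinstance(effects, dict):
        raise ConfigError("effects must be a mapping of effect names to values")
    try:
        eff = CaseStudyEffects(**effects)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
    kwargs = {k: v for k, v in raw.items() if k != "effects"}
    return CaseStudyConfig(effects=eff, **kwargs)


def load_config(path):
    """Load a YAML config; defaults fill omitted keys, unknown keys reject.

    An empty file yields the full default scenario-A grid (all three sample
    sizes, 10,000 replicates).  A top-level ``command: case-study`` key
    switches to the case-study schema.
    """
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"could not parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    command = raw.pop("command", "simulate")
    if command == "simulate":
        return _build_grid(raw)
    if command in ("case-study", "case_study"):
        return _build_case(raw)
    raise ConfigError(f"unknown command {command!r}")


def grid_to_dict(grid: StudyGrid) -> dict:
    """Serializable resolved-config mapping (round-trips via load_config)."""
    return {
        "command": "simulate",
        "scenario": grid.scenario,
        "sample_sizes": list(grid.sample_sizes),
        "n_reps": grid.n_reps,
        "adjustment_conditions": [list(a.covariates)
                                  for a in grid.adjustment_conditions],
        "beta1_values": [float(b) for b in grid.beta1_values],
        "base_seed": grid.base_seed,
    }


def write_config(grid: StudyGrid, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(grid_to_dict(grid), fh, sort_keys=False)
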