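"""YAML configuration handling for scenarios and grids.

Scenario file layout (keys map one-to-one onto the domain types)::

    prevalence: {true: 0.4, assumed: 0.2}
    tests:
      A: {se: 0.95, sp: 0.90}
      B: {se: 0.70, sp: 0.75}
    outcomes:
      kind: binary
      mu: {I_pos: 0.1, II_pos: 0.25, I_neg: 0.2, II_neg: 0.05}
    design: {alpha: 0.05, power: 0.8, interim_fraction: 0.5}
    hypothesis: alternative        # optional

A continuous outcome instead uses::

    outcomes:
      kind: continuous
      means: {tp: 2, fn: 5, fp: 4, tn: 1}
      sd: 2
      planning_delta: 0.2          # optional override of the model-implied effect

A grid file nests ``grid:`` (value lists / fixed values, names as in
:class:`~testtreat.scenario_engine.GridConfig`) and ``run:``
(reps, seed, alpha, power, interim_fraction, n_max_factor).
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .design_model import (
    BinaryOutcomeModel,
    ContinuousOutcomeModel,
    DesignParams,
    ScenarioSpec,
    TestAccuracy,
)
from .errors import ValidationError
from .scenario_engine import GridConfig, FACTOR_COLUMNS

__all__ = ["load_scenario", "scenario_to_dict", "dump_scenario", "load_grid", "grid_to_dict"]


def _require(mapping: dict, key: str, context: str):
    try:
        return mapping[key]
    except (KeyError, TypeError):
        raise ValidationError(f"missing key {key!r} in {context} section") from None


def scenario_from_dict(data: dict) -> ScenarioSpec:
    prevalence = _require(data, "prevalence", "scenario")
    if isinstance(prevalence, dict):
        # YAML parses a bare `true:` key as a boolean; accept both spellings
        prevalence = {str(key).lower(): value for key, value in prevalence.items()}
    tests = _require(data, "tests", "scenario")
    outcomes_cfg = _require(data, "outcomes", "scenario")
    kind = _require(outcomes_cfg, "kind", "outcomes")
    planning_delta = None
    if kind == "binary":
        mu = _require(outcomes_cfg, "mu", "outcomes")
        outcomes = BinaryOutcomeModel(
            mu_I_pos=_require(mu, "I_pos", "mu"),
            mu_II_pos=_require(mu, "II_pos", "mu"),
            mu_I_neg=_require(mu, "I_neg", "mu"),
            mu_II_neg=_require(mu, "II_neg", "mu"),
        )
    elif kind == "continuous":
        means = _require(outcomes_cfg, "means", "outcomes")
        outcomes = ContinuousOutcomeModel(
            mean_tp=_require(means, "tp", "means"),
            mean_fn=_require(means, "fn", "means"),
            mean_fp=_require(means, "fp", "means"),
            mean_tn=_require(means, "tn", "means"),
            sd=_require(outcomes_cfg, "sd", "outcomes"),
        )
        planning_delta = outcomes_cfg.get("planning_delta")
    else:
        raise ValidationError(f"unknown outcomes kind {kind!r}")
    design_cfg = data.get("design", {})
    return ScenarioSpec(
        pi_true=_require(prevalence, "true", "prevalence"),
        pi_assumed=_require(prevalence, "assumed", "prevalence"),
        acc_A=TestAccuracy(**_require(tests, "A", "tests")),
        acc_B=TestAccuracy(**_require(tests, "B", "tests")),
        outcomes=outcomes,
        design=DesignParams(**design_cfg),
        hypothesis=data.get("hypothesis", "alternative"),
        planning_delta=planning_delta,
    )


def scenario_to_dict(scenario: ScenarioSpec) -> dict:
    """Serialize a scenario so that parse -> serialize -> parse is identity."""
    if scenario.is_binary:
        outcomes = {
            "kind": "binary",
            "mu": {
                "I_pos": scenario.outcomes.mu_I_pos,
                "II_pos": scenario.outcomes.mu_II_pos,
                "I_neg": scenario.outcomes.mu_I_neg,
                "II_neg": scenario.outcomes.mu_II_neg,
            },
        }
    else:
        outcomes = {
            "kind": "continuous",
            "means": {
                "tp": scenario.outcomes.mean_tp,
                "fn": scenario.outcomes.mean_fn,
                "fp": scenario.outcomes.mean_fp,
                "tn": scenario.outcomes.mean_tn,
            },
            "sd": scenario.outcomes.sd,
        }
        if scenario.planning_delta is not None:
            outcomes["planning_delta"] = scenario.planning_delta
    return {
        "prevalence": {"true": scenario.pi_true, "assumed": scenario.pi_assumed},
        "tests": {
            "A": {"se": scenario.acc_A.se, "sp": scenario.acc_A.sp},
            "B": {"se": scenario.acc_B.se, "sp": scenario.acc_B.sp},
        },
        "outcomes": outcomes,
        "design": asdict(scenario.design),
        "hypothesis": scenario.hypothesis,
    }


def load_scenario(path) -> ScenarioSpec:
    with open(path) as handle:
        data = yaml.safe_load(handle)
    if not isinstance(data, dict):
        raise ValidationError(f"scenario file {path} is not a mapping")
    return scenario_from_dict(data)


def dump_scenario(scenario: ScenarioSpec, path) -> None:
    Path(path).write_text(yaml.safe_dump(scenario_to_dict(scenario), sort_keys=False))


def grid_from_dict(data: dict) -> GridConfig:
    grid = dict(data.get("grid", {}))
    run = dict(data.get("run", {}))
    kwargs = {}
    for name in FACTOR_COLUMNS:
        if name in grid:
            kwargs[name] = tuple(grid.pop(name))
    for name in ("mu_II_pos", "mu_I_neg", "mu_II_neg"):
        if name in grid:
            kwargs[name] = grid.pop(name)
    if grid:
        raise ValidationError(f"unknown grid keys: {sorted(grid)}")
    for name in ("reps", "seed", "alpha", "power", "interim_fraction", "n_max_factor"):
        if name in run:
            kwargs[name] = run.pop(name)
    if run:
        raise ValidationError(f"unknown run keys: {sorted(run)}")
    return GridConfig(**kwargs)


def grid_to_dict(config: GridConfig) -> dict:
    return {
        "grid": {
            **{name: list(getattr(config, name)) for name in FACTOR_COLUMNS},
            "mu_II_pos": config.mu_II_pos,
            "mu_I_neg": config.mu_I_neg,
            "mu_II_neg": config.mu_II_neg,
        },
        "run": {
            "reps": config.reps,
            "seed": config.seed,
            "alpha": config.alpha,
            "power": config.power,
            "interim_fraction": config.interim_fraction,
            "n_max_factor": config.n_max_factor,
        },
    }


def load_grid(path) -> GridConfig:
    with open(path) as handle:
        data = yaml.safe_load(handle)
    if not isinstance(data, dict):
        raise ValidationError(f"grid file {path} is not a mapping")
    return grid_from_dict(data)
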