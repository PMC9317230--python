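"""Factorial scenario grid and vectorized Monte-Carlo operating characteristics.

The study design of interest is evaluated over a full factorial grid of
worlds (true and assumed prevalence, accuracies of both tests, outcome of
management I in the diseased).  For each scenario the engine runs many
replications of the adaptive design (internal pilot, blinded prevalence
re-estimation, recalculated final size) and of the fixed design, under the
alternative hypothesis and under a matched null twin, and summarizes:

* empirical power / type-I error: fraction of replications whose two-sided
  unpooled Wald test rejects at level alpha;
* relative bias of the interim prevalence estimate, in percent of truth;
* the distribution of the planned (N0), recalculated (N*) and final sample
  sizes, and the ratios N*/N_required and N0/N*.

All replications of one (scenario, hypothesis, design) triple are simulated
as vectorized binomial draws on the aggregated cell representation, which
is statistically equivalent to the per-patient generator (checked in the
test suite) and fast enough for the full grid at desk scale.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .blinded_recalc import interim_size
from .design_model import (
    BinaryOutcomeModel,
    DesignParams,
    ScenarioSpec,
    TestAccuracy,
    expected_event_rate,
)
from .errors import DegenerateEffectError, ValidationError
from .sample_size import planned_size, required_size, two_proportions_raw

__all__ = [
    "GridConfig",
    "OperatingCharacteristics",
    "build_grid",
    "run_scenario",
    "run_grid",
    "relative_bias",
    "summarize",
]

logger = logging.getLogger(__name__)

FACTOR_COLUMNS = ["pi_true", "pi_assumed", "se_A", "sp_A", "se_B", "sp_B", "mu_I_pos"]


@dataclass(frozen=True)
class GridConfig:
    """Value lists of the factorial simulation grid and run parameters.

    The default lists reproduce the 2 x 5 x 3^4 x 2 = 1620-scenario layout.
    The four accuracy values quoted for the recalculation-gain scenario
    (Se_A 0.95, Sp_A 0.90, Se_B 0.70, Sp_B 0.75), both mu_I+ values and the
    fixed subgroup outcomes are known; the remaining list entries are
    declared assumptions and can be overridden.
    """

    pi_true: tuple = (0.2, 0.4)
    pi_assumed: tuple = (0.1, 0.2, 0.3, 0.4, 0.5)
    se_A: tuple = (0.8, 0.9, 0.95)
    sp_A: tuple = (0.8, 0.9, 0.95)
    se_B: tuple = (0.6, 0.7, 0.8)
    sp_B: tuple = (0.6, 0.75, 0.9)
    mu_I_pos: tuple = (0.05, 0.1)
    mu_II_pos: float = 0.25
    mu_I_neg: float = 0.2
    mu_II_neg: float = 0.05
    reps: int = 10_000
    interim_fraction: float = 0.5
    alpha: float = 0.05
    power: float = 0.80
    seed: int = 0
    n_max_factor: int = 10

    def __post_init__(self) -> None:
        for name in FACTOR_COLUMNS:
            values = getattr(self, name)
            if not isinstance(values, (tuple, list)) or len(values) == 0:
                raise ValidationError(f"factor {name} needs a non-empty value list")
        if self.reps < 1:
            raise ValidationError("reps must be at least 1")

    @property
    def n_scenarios(self) -> int:
        return math.prod(len(getattr(self, name)) for name in FACTOR_COLUMNS)


def build_grid(config: GridConfig) -> list[ScenarioSpec]:
    """Full factorial list of alternative-hypothesis scenarios.

    Each scenario's null twin is available via :meth:`ScenarioSpec.null_twin`
    (same parameters, data generated with no arm difference).
    """
    design = DesignParams(
        alpha=config.alpha, power=config.power, interim_fraction=config.interim_fraction
    )
    scenarios = []
    for pi_true, pi_assumed, se_a, sp_a, se_b, sp_b, mu_i_pos in itertools.product(
        *(getattr(config, name) for name in FACTOR_COLUMNS)
    ):
        scenarios.append(
            ScenarioSpec(
                pi_true=pi_true,
                pi_assumed=pi_assumed,
                acc_A=TestAccuracy(se=se_a, sp=sp_a),
                acc_B=TestAccuracy(se=se_b, sp=sp_b),
                outcomes=BinaryOutcomeModel(
                    mu_I_pos=mu_i_pos,
                    mu_II_pos=config.mu_II_pos,
                    mu_I_neg=config.mu_I_neg,
                    mu_II_neg=config.mu_II_neg,
                ),
                design=design,
            )
        )
    return scenarios


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Per-(scenario, design, hypothesis) Monte-Carlo summaries."""

    scenario_id: int
    design_kind: str
    hypothesis: str
    reps: int
    rejection_rate: float
    n0: int
    n_required: int
    pi_hat_mean: float = float("nan")
    pi_hat_rel_bias_pct: float = float("nan")
    n_star_mean: float = float("nan")
    n_star_sd: float = float("nan")
    n_final_mean: float = float("nan")
    n_final_sd: float = float("nan")
    ratio_nstar_required_mean: float = float("nan")
    ratio_n0_nstar_mean: float = float("nan")
    capped_fraction: float = 0.0


def relative_bias(pi_hat_mean: float, pi_true: float) -> float:
    """Relative bias of the prevalence estimate, ((mean - pi) / pi) * 100%."""
    if pi_true <= 0:
        raise ValidationError("pi_true must be positive for a relative bias")
    return (pi_hat_mean - pi_true) / pi_true * 100.0


def _arm_draws(rng, n_arm, pi, acc, mu, size=None):
    """Vectorized cell draws for one arm: (diseased, events) arrays."""
    d = rng.binomial(n_arm, pi, size=size)
    n_healthy = n_arm - d
    tp = rng.binomial(d, acc.se)
    fp = rng.binomial(n_healthy, 1.0 - acc.sp)
    x = (
        rng.binomial(tp, mu.mu_I_pos)
        + rng.binomial(d - tp, mu.mu_II_pos)
        + rng.binomial(fp, mu.mu_I_neg)
        + rng.binomial(n_healthy - fp, mu.mu_II_neg)
    )
    return d, x


def _wald_reject(x_a, n_a, x_b, n_b, alpha):
    """Vectorized strict-rejection indicator of the unpooled Wald test."""
    from scipy import stats

    p_a = x_a / n_a
    p_b = x_b / n_b
    var = p_a * (1.0 - p_a) / n_a + p_b * (1.0 - p_b) / n_b
    z = np.zeros_like(var, dtype=float)
    ok = var > 0
    z[ok] = (p_a[ok] - p_b[ok]) / np.sqrt(var[ok])
    p = 2.0 * stats.norm.sf(np.abs(z))
    p[~ok] = 1.0
    return p < alpha


def _seed_to_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def run_scenario(
    scenario: ScenarioSpec,
    reps: int,
    seed,
    designs: Sequence[str] = ("adaptive", "fixed"),
    scenario_id: int = 0,
    n_max: int | None = None,
) -> dict[str, OperatingCharacteristics]:
    """Monte-Carlo operating characteristics of one scenario.

    Raises :class:`DegenerateEffectError` if the planned or true-necessary
    sample size does not exist (zero effect at the assumed or the true
    prevalence); such scenarios carry no meaningful power.
    """
    rng = _seed_to_rng(seed)
    n0 = planned_size(scenario).n_total
    n_req = required_size(scenario).n_total
    if n_max is None:
        n_max = 10 * n0
    alpha = scenario.design.alpha
    mu = scenario.outcomes
    gen_a, gen_b = scenario.generating_accuracies()
    out: dict[str, OperatingCharacteristics] = {}

    for design_kind in designs:
        if design_kind == "fixed":
            d_a, x_a = _arm_draws(rng, n0 // 2, scenario.pi_true, gen_a, mu, size=reps)
            d_b, x_b = _arm_draws(rng, n0 // 2, scenario.pi_true, gen_b, mu, size=reps)
            reject = _wald_reject(
                x_a, np.full(reps, n0 // 2), x_b, np.full(reps, n0 // 2), alpha
            )
            out[design_kind] = OperatingCharacteristics(
                scenario_id=scenario_id,
                design_kind="fixed",
                hypothesis=scenario.hypothesis,
                reps=reps,
                rejection_rate=float(reject.mean()),
                n0=n0,
                n_required=n_req,
                n_final_mean=float(n0),
                n_final_sd=0.0,
            )
            continue
        if design_kind != "adaptive":
            raise ValidationError(f"unknown design kind {design_kind!r}")

        n1 = interim_size(n0, scenario.design.interim_fraction)
        n1_arm = n1 // 2
        d_a1, x_a1 = _arm_draws(rng, n1_arm, scenario.pi_true, gen_a, mu, size=reps)
        d_b1, x_b1 = _arm_draws(rng, n1_arm, scenario.pi_true, gen_b, mu, size=reps)
        pi_hat = (d_a1 + d_b1) / n1

        # blinded recalculation at pi_hat with the alternative-hypothesis
        # (planning) accuracies and outcome parameters
        theta_a = expected_event_rate(pi_hat, scenario.acc_A, mu)
        theta_b = expected_event_rate(pi_hat, scenario.acc_B, mu)
        raw = two_proportions_raw(theta_a, theta_b, alpha, scenario.design.power)
        n_star = 2.0 * np.ceil(raw)
        bad = ~np.isfinite(n_star)
        capped = bad | (n_star > n_max)
        n_star = np.where(capped, n_max, n_star).astype(np.int64)
        n_final = np.maximum(n1, n_star)

        n2_arm = (n_final - n1) // 2
        d_a2, x_a2 = _arm_draws(rng, n2_arm, scenario.pi_true, gen_a, mu)
        d_b2, x_b2 = _arm_draws(rng, n2_arm, scenario.pi_true, gen_b, mu)
        n_arm_final = n_final // 2
        reject = _wald_reject(x_a1 + x_a2, n_arm_final, x_b1 + x_b2, n_arm_final, alpha)

        ratio_req = n_star / n_req
        ratio_n0 = n0 / n_star
        out[design_kind] = OperatingCharacteristics(
            scenario_id=scenario_id,
            design_kind="adaptive",
            hypothesis=scenario.hypothesis,
            reps=reps,
            rejection_rate=float(reject.mean()),
            n0=n0,
            n_required=n_req,
            pi_hat_mean=float(pi_hat.mean()),
            pi_hat_rel_bias_pct=relative_bias(float(pi_hat.mean()), scenario.pi_true),
            n_star_mean=float(n_star.mean()),
            n_star_sd=float(n_star.std(ddof=1)) if reps > 1 else 0.0,
            n_final_mean=float(n_final.mean()),
            n_final_sd=float(n_final.std(ddof=1)) if reps > 1 else 0.0,
            ratio_nstar_required_mean=float(ratio_req.mean()),
            ratio_n0_nstar_mean=float(ratio_n0.mean()),
            capped_fraction=float(capped.mean()),
        )
    return out


#: effects smaller than this (absolute difference in event rates) are treated
#: as zero when deciding whether a grid scenario has a sample size at all
DEGENERATE_EFFECT_TOL = 1e-9


def _is_degenerate(scenario: ScenarioSpec) -> bool:
    """True when the effect vanishes at the assumed or the true prevalence
    (up to floating-point noise), so no finite sample size exists."""
    from .design_model import effect_size

    return (
        abs(effect_size(scenario, scenario.pi_assumed)) < DEGENERATE_EFFECT_TOL
        or abs(effect_size(scenario, scenario.pi_true)) < DEGENERATE_EFFECT_TOL
    )


def run_grid(
    config: GridConfig,
    designs: Sequence[str] = ("adaptive", "fixed"),
    hypotheses: Sequence[str] = ("alternative", "null"),
    reps: int | None = None,
) -> tuple[pd.DataFrame, int]:
    """Run every (scenario, hypothesis, design) combination of the grid.

    Returns a scenario-level table (one row per combination, factor values
    plus all :class:`OperatingCharacteristics` fields) and the count of
    scenarios skipped because their effect is exactly degenerate at the
    assumed or true prevalence.
    """
    if reps is None:
        reps = config.reps
    scenarios = build_grid(config)
    rows = []
    skipped = 0
    root = np.random.SeedSequence(config.seed)
    for i, scenario in enumerate(scenarios):
        if _is_degenerate(scenario):
            skipped += 1
            continue
        for h_idx, hypothesis in enumerate(hypotheses):
            spec = scenario if hypothesis == "alternative" else scenario.null_twin()
            for d_idx, design_kind in enumerate(designs):
                seed = np.random.SeedSequence(
                    entropy=config.seed, spawn_key=(i, h_idx, d_idx)
                )
                oc = run_scenario(
                    spec,
                    reps,
                    np.random.default_rng(seed),
                    designs=(design_kind,),
                    scenario_id=i,
                    n_max=config.n_max_factor * planned_size(spec).n_total,
                )[design_kind]
                row = {
                    "pi_true": scenario.pi_true,
                    "pi_assumed": scenario.pi_assumed,
                    "se_A": scenario.acc_A.se,
                    "sp_A": scenario.acc_A.sp,
                    "se_B": scenario.acc_B.se,
                    "sp_B": scenario.acc_B.sp,
                    "mu_I_pos": scenario.outcomes.mu_I_pos,
                }
                row.update(asdict(oc))
                rows.append(row)
    if skipped:
        logger.info("skipped %d degenerate scenarios (zero effect)", skipped)
    return pd.DataFrame(rows), skipped


def summarize(results: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Median operating characteristics, overall and stratified.

    Stratification keys follow the study's figures: prevalence
    misspecification (pi_assumed - pi_true), sensitivity difference
    (se_A - se_B), specificity difference (sp_A - sp_B) and mu_I+.
    """
    if results.empty:
        raise ValidationError("no results to summarize")
    df = results.copy()
    # round the derived differences so equal strata are not split by
    # floating-point noise (0.3 - 0.4 vs 0.1 - 0.2)
    df["d_prevalence"] = (df["pi_assumed"] - df["pi_true"]).round(10)
    df["d_sensitivity"] = (df["se_A"] - df["se_B"]).round(10)
    df["d_specificity"] = (df["sp_A"] - df["sp_B"]).round(10)
    keys = ["design_kind", "hypothesis"]
    overall = (
        df.groupby(keys)["rejection_rate"].median().rename("median_rejection_rate").reset_index()
    )
    tables: dict[str, pd.DataFrame] = {"overall": overall}
    for stratum in ("d_prevalence", "d_sensitivity", "d_specificity", "mu_I_pos"):
        tables[stratum] = (
            df.groupby(keys + [stratum])["rejection_rate"]
            .median()
            .rename("median_rejection_rate")
            .reset_index()
        )
    return tables
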