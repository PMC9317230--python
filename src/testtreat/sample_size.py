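"""Deterministic sample-size calculations.

Two endpoints are covered:

* binary — the normal-approximation formula for comparing two independent
  binomial proportions in a balanced design,

      n_per_arm = [ sqrt(2 * tbar * (1 - tbar)) * z_{1-alpha/2}
                  + sqrt(tA(1-tA) + tB(1-tB)) * z_{1-beta} ]^2 / Delta^2,

  with ``tbar`` the overall (pooled) response rate and ``Delta = tA - tB``;

* continuous — the two-independent-means formula, either the normal
  approximation ``n = 2 sd^2 (z_{1-alpha/2} + z_{1-beta})^2 / Delta^2`` or
  the iterative refinement that replaces normal quantiles with t quantiles
  at 2n-2 degrees of freedom (the default for continuous endpoints).

Per-arm values are rounded up to the next integer, so totals are even.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

from scipy import stats

from .design_model import ScenarioSpec, pooled_rate
from .errors import DegenerateEffectError, ValidationError

__all__ = [
    "SampleSizeResult",
    "n_two_proportions",
    "n_two_means",
    "planned_size",
    "required_size",
]


@dataclass(frozen=True)
class SampleSizeResult:
    """Per-arm and total sample size, plus the unrounded per-arm requirement."""

    n_per_arm: int
    n_total: int
    raw_value: float

    def __post_init__(self) -> None:
        if self.n_per_arm != math.ceil(self.raw_value):
            raise ValidationError("n_per_arm must be the ceiling of raw_value")
        if self.n_total != 2 * self.n_per_arm:
            raise ValidationError("n_total must equal 2 * n_per_arm")


@lru_cache(maxsize=None)
def normal_quantiles(alpha: float, power: float) -> tuple[float, float]:
    """(z_{1-alpha/2}, z_{1-beta}) for a two-sided level and target power."""
    return (
        float(stats.norm.ppf(1.0 - alpha / 2.0)),
        float(stats.norm.ppf(power)),
    )


def _result(raw: float) -> SampleSizeResult:
    n_arm = max(1, math.ceil(raw))
    return SampleSizeResult(n_per_arm=n_arm, n_total=2 * n_arm, raw_value=raw)


def two_proportions_raw(theta_A: float, theta_B: float, alpha: float, power: float) -> float:
    """Unrounded per-arm requirement of the two-proportion formula.

    Accepts scalars or numpy arrays for the rates (used by the vectorized
    simulation engine); no rounding, no validation beyond what the math
    itself enforces.
    """
    import numpy as np

    z_a, z_b = normal_quantiles(alpha, power)
    theta_A = np.asarray(theta_A, dtype=float)
    theta_B = np.asarray(theta_B, dtype=float)
    tbar = 0.5 * (theta_A + theta_B)
    delta = theta_A - theta_B
    with np.errstate(divide="ignore", invalid="ignore"):
        num = (
            np.sqrt(2.0 * tbar * (1.0 - tbar)) * z_a
            + np.sqrt(theta_A * (1.0 - theta_A) + theta_B * (1.0 - theta_B)) * z_b
        ) ** 2
        raw = num / delta**2
    return raw if raw.ndim else float(raw)


def n_two_proportions(
    theta_A: float, theta_B: float, alpha: float = 0.05, power: float = 0.80
) -> SampleSizeResult:
    """Per-arm/total sample size for detecting theta_A != theta_B.

    Raises
    ------
    DegenerateEffectError
        If the two rates coincide (the required size is infinite).
    ValidationError
        If either rate sits on the boundary 0 or 1 (zero-variance arms).
    """
    for name, t in (("theta_A", theta_A), ("theta_B", theta_B)):
        if not 0.0 < t < 1.0:
            raise ValidationError(f"{name} must lie strictly inside (0, 1), got {t!r}")
    if theta_A == theta_B:
        raise DegenerateEffectError(
            "theta_A equals theta_B: no effect to detect, required size is infinite"
        )
    pooled_rate(theta_A, theta_B)  # re-validates as probabilities
    return _result(two_proportions_raw(theta_A, theta_B, alpha, power))


def _two_means_raw_normal(delta: float, sd: float, alpha: float, power: float) -> float:
    z_a, z_b = normal_quantiles(alpha, power)
    return 2.0 * sd**2 * (z_a + z_b) ** 2 / delta**2


def n_two_means(
    delta: float,
    sd: float,
    alpha: float = 0.05,
    power: float = 0.80,
    method: str = "t_iterative",
) -> SampleSizeResult:
    """Per-arm/total sample size for comparing two independent means.

    ``method='normal'`` uses normal quantiles; ``method='t_iterative'``
    (default) finds the smallest integer n per arm satisfying

        n >= 2 sd^2 (t_{1-alpha/2, 2n-2} + t_{1-beta, 2n-2})^2 / delta^2,

    starting from the normal solution.  Invariant to the sign of ``delta``.
    """
    if delta == 0:
        raise DegenerateEffectError("delta is zero: required size is infinite")
    if sd <= 0:
        raise ValidationError(f"sd must be positive, got {sd!r}")
    if method not in ("normal", "t_iterative"):
        raise ValidationError(f"unknown method {method!r}")

    raw_normal = _two_means_raw_normal(delta, sd, alpha, power)
    if method == "normal":
        return _result(raw_normal)

    def requirement(n: int) -> float:
        df = max(2 * n - 2, 1)
        t_a = stats.t.ppf(1.0 - alpha / 2.0, df)
        t_b = stats.t.ppf(power, df)
        return 2.0 * sd**2 * (t_a + t_b) ** 2 / delta**2

    n = max(2, math.ceil(raw_normal))
    for _ in range(100):
        req = requirement(n)
        if n >= req:
            break
        n = math.ceil(req)
    # walk back in case the fixed point overshot the smallest admissible n
    while n > 2 and (n - 1) >= requirement(n - 1):
        n -= 1
    raw = requirement(n)
    if math.ceil(raw) != n:  # keep the ceiling invariant at discreteness edges
        raw = float(n)
    return SampleSizeResult(n_per_arm=n, n_total=2 * n, raw_value=raw)


def _scenario_size(scenario: ScenarioSpec, pi: float, delta: float | None) -> SampleSizeResult:
    if scenario.is_binary:
        theta_a, theta_b = scenario.arm_rates(pi)
        return n_two_proportions(
            theta_a, theta_b, scenario.design.alpha, scenario.design.power
        )
    if delta is None:
        theta_a, theta_b = scenario.arm_rates(pi)
        delta = theta_a - theta_b
    if delta == 0:
        raise DegenerateEffectError("model-implied delta is zero at this prevalence")
    return n_two_means(
        delta,
        scenario.outcomes.sd,
        scenario.design.alpha,
        scenario.design.power,
        method="t_iterative",
    )


def planned_size(scenario: ScenarioSpec, delta: float | None = None) -> SampleSizeResult:
    """Initial sample size N0, computed at the assumed prevalence.

    For continuous endpoints an explicit ``delta`` (or the scenario's
    ``planning_delta``) overrides the model-implied effect, matching the
    common practice of planning on a rounded clinically-stated difference.
    """
    if delta is None:
        delta = scenario.planning_delta
    return _scenario_size(scenario, scenario.pi_assumed, delta)


def required_size(scenario: ScenarioSpec) -> SampleSizeResult:
    """True necessary sample size: the formula evaluated at the true prevalence."""
    return _scenario_size(scenario, scenario.pi_true, None)
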