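"""Blinded sample size recalculation from an internal pilot study.

The prevalence is the nuisance parameter: it moves the required sample size
but reveals nothing about the between-arm difference, so re-estimating it at
interim keeps the trial blinded and the final test is run at the unadjusted
significance level.  The procedure has three steps:

1. plan N0 from the assumed prevalence (and assumed accuracies/outcomes);
2. recruit the internal pilot of N1 = N0 * f patients and estimate the
   prevalence, either as the binomial ML estimator n / N1 from the reference
   standard, or — when no reference standard is available but the test
   accuracies are trusted — by inverting the overall positive rate;
3. recompute the sample size at the estimated prevalence and recruit up to
   n_final = max(N1, N*).  Patients already recruited are never discarded.

Nothing in this module consumes outcomes or arm labels: the interim snapshot
carries only reference-standard counts or a pooled positive rate, which is
what keeps the recalculation blinded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .design_model import ScenarioSpec
from .errors import (
    DegenerateEffectError,
    EmptyInterimError,
    UninformativeTestsError,
    ValidationError,
)
from .sample_size import planned_size, n_two_proportions, n_two_means

__all__ = [
    "InterimSnapshot",
    "RecalcResult",
    "interim_size",
    "estimate_prevalence_mle",
    "invert_positive_rate",
    "prevalence_from_positive_rate",
    "recalculate",
]


@dataclass(frozen=True)
class InterimSnapshot:
    """Blinded interim information: pilot size plus either the number of
    reference-standard positives or the pooled fraction testing positive."""

    n1: int
    n_pos_ref: int | None = None
    p_obs: float | None = None

    def __post_init__(self) -> None:
        if self.n1 < 0:
            raise ValidationError("n1 must be non-negative")
        if self.n_pos_ref is not None and not 0 <= self.n_pos_ref <= self.n1:
            raise ValidationError("n_pos_ref must lie in [0, n1]")
        if self.p_obs is not None and not 0.0 <= self.p_obs <= 1.0:
            raise ValidationError("p_obs must lie in [0, 1]")


@dataclass(frozen=True)
class RecalcResult:
    """Outcome of one blinded recalculation."""

    n0: int
    n1: int
    pi_hat: float
    n_star: int
    n_final: int
    capped: bool = False

    def __post_init__(self) -> None:
        if self.n_final != max(self.n1, self.n_star):
            raise ValidationError("n_final must equal max(n1, n_star)")


def interim_size(n0: int, f: float) -> int:
    """Internal pilot size N1 = N0 * f, rounded up to the next even integer
    so both arms fill under 1:1 allocation."""
    if not 0.0 < f < 1.0:
        raise ValidationError(f"interim fraction must lie in (0, 1), got {f!r}")
    if n0 < 2:
        raise ValidationError("n0 must be at least 2")
    n1 = math.ceil(n0 * f)
    if n1 % 2:
        n1 += 1
    return n1


def estimate_prevalence_mle(snapshot: InterimSnapshot) -> float:
    """Binomial maximum-likelihood prevalence estimate n / N1 from the
    reference-standard positives in the internal pilot."""
    if snapshot.n1 == 0:
        raise EmptyInterimError("cannot estimate a prevalence from zero patients")
    if snapshot.n_pos_ref is None:
        raise ValidationError("snapshot carries no reference-standard count")
    return snapshot.n_pos_ref / snapshot.n1


def invert_positive_rate(p_plus: float, acc_A, acc_B) -> float:
    """Invert the overall positive rate P+ (summed over both tests) to the
    prevalence:

        pi = (P+ + Sp_A + Sp_B - 2) / (Youden_A + Youden_B).

    ``p_plus`` must lie in its attainable range
    [(1-Sp_A) + (1-Sp_B), Se_A + Se_B].
    """
    youden_sum = acc_A.youden + acc_B.youden
    if youden_sum == 0.0:
        raise UninformativeTestsError(
            "summed Youden index is zero: the positive rate carries no prevalence information"
        )
    lo = (1.0 - acc_A.sp) + (1.0 - acc_B.sp)
    hi = acc_A.se + acc_B.se
    if youden_sum < 0:
        lo, hi = hi, lo
    if not lo - 1e-12 <= p_plus <= hi + 1e-12:
        raise ValidationError(
            f"P+ = {p_plus!r} outside its attainable range [{lo}, {hi}]"
        )
    pi = (p_plus + acc_A.sp + acc_B.sp - 2.0) / youden_sum
    return min(1.0, max(0.0, pi))


def prevalence_from_positive_rate(p_obs: float, acc_A, acc_B) -> float:
    """Prevalence from the observed pooled positive fraction.

    Under 1:1 allocation the observed fraction of positive test results in
    the pooled interim sample estimates P+ / 2 (P+ sums the per-test positive
    probabilities), so the inversion uses P+ = 2 * p_obs.
    """
    if not 0.0 <= p_obs <= 1.0:
        raise ValidationError("p_obs must lie in [0, 1]")
    return invert_positive_rate(2.0 * p_obs, acc_A, acc_B)


def recalculate(
    scenario: ScenarioSpec,
    pi_hat: float,
    n1: int,
    n_max: int | None = None,
    planning_delta: float | None = None,
) -> RecalcResult:
    """Step 3 of the procedure: recompute the sample size at ``pi_hat``.

    The recalculation substitutes the estimated prevalence into the sample
    size formula while keeping the (true, alternative-hypothesis) accuracy
    and outcome parameters.  The final size is max(N1, N*): patients already
    in the pilot are retained, and the analysis level alpha is unchanged.

    A degenerate interim estimate (effect ~ 0 at ``pi_hat``, or a boundary
    estimate) would send N* to infinity; instead N* is capped at ``n_max``
    (default 10 * N0) and flagged, so replication loops never abort.
    """
    if not 0.0 <= pi_hat <= 1.0:
        raise ValidationError("pi_hat must lie in [0, 1]")
    n0 = planned_size(scenario, delta=planning_delta).n_total
    if n_max is None:
        n_max = 10 * n0
    capped = False
    try:
        if scenario.is_binary:
            theta_a, theta_b = scenario.arm_rates(pi_hat)
            n_star = n_two_proportions(
                theta_a, theta_b, scenario.design.alpha, scenario.design.power
            ).n_total
        else:
            theta_a, theta_b = scenario.arm_rates(pi_hat)
            n_star = n_two_means(
                theta_a - theta_b,
                scenario.outcomes.sd,
                scenario.design.alpha,
                scenario.design.power,
            ).n_total
    except (DegenerateEffectError, ValidationError):
        n_star = n_max
        capped = True
    if n_star > n_max:
        n_star = n_max
        capped = True
    return RecalcResult(
        n0=n0, n1=n1, pi_hat=pi_hat, n_star=n_star,
        n_final=max(n1, n_star), capped=capped,
    )
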