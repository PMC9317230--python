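"""Probabilistic model of a randomized test-treatment arm.

A test-treatment trial randomizes patients between two diagnostic tests A
and B; each test result triggers a management strategy (positives receive
management I, negatives management II) and the patient outcome is evaluated
afterwards.  The expected outcome of one arm therefore mixes the subgroup
outcomes over the joint distribution of disease status and test result:

    theta_t = pi * [Se_t * mu_I+ + (1 - Se_t) * mu_II+]
            + (1 - pi) * [(1 - Sp_t) * mu_I- + Sp_t * mu_II-]

where ``pi`` is the prevalence P(D=+), ``Se_t``/``Sp_t`` the accuracy of the
test applied in that arm and ``mu_md`` the expected outcome of management
``m`` in disease stratum ``d``.  The subgroup outcomes are shared between
arms (no test-by-treatment interaction), so any arm difference is driven
purely by how accurately each test routes patients to the management that
suits their true disease state.

The same structure applies to a continuous endpoint by replacing the event
probabilities with cell means (true positive / false negative / false
positive / true negative).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Union

import numpy as np

from .errors import ValidationError

__all__ = [
    "TestAccuracy",
    "BinaryOutcomeModel",
    "ContinuousOutcomeModel",
    "ManagementRule",
    "DesignParams",
    "ScenarioSpec",
    "expected_event_rate",
    "expected_mean_response",
    "effect_size",
    "pooled_rate",
]


def _check_prob(value: float, name: str, *, open_interval: bool = False) -> None:
    arr = np.asarray(value, dtype=float)
    if open_interval:
        ok = np.all((arr > 0.0) & (arr < 1.0))
    else:
        ok = np.all((arr >= 0.0) & (arr <= 1.0))
    if not ok:
        bounds = "(0, 1)" if open_interval else "[0, 1]"
        raise ValidationError(f"{name} must lie in {bounds}, got {value!r}")


@dataclass(frozen=True)
class TestAccuracy:
    """Sensitivity and specificity of one binary diagnostic test.

    ``se`` is P(R=+ | D=+), ``sp`` is P(R=- | D=-).
    """

    se: float
    sp: float

    __test__ = False  # not a test class despite the name

    def __post_init__(self) -> None:
        _check_prob(self.se, "sensitivity")
        _check_prob(self.sp, "specificity")

    @property
    def youden(self) -> float:
        """Youden index Se + Sp - 1."""
        return self.se + self.sp - 1.0


@dataclass(frozen=True)
class BinaryOutcomeModel:
    """Event probabilities mu_md per management (I/II) x disease (+/-) cell.

    Shared between the two arms: the effect of a correct (or incorrect)
    management decision does not depend on which test produced it.
    """

    mu_I_pos: float
    mu_I_neg: float
    mu_II_pos: float
    mu_II_neg: float

    def __post_init__(self) -> None:
        for name in ("mu_I_pos", "mu_I_neg", "mu_II_pos", "mu_II_neg"):
            _check_prob(getattr(self, name), name)

    def mu(self, management: str, diseased: bool) -> float:
        """Event probability for a management ('I'/'II') x disease cell."""
        key = f"mu_{management}_{'pos' if diseased else 'neg'}"
        return getattr(self, key)


@dataclass(frozen=True)
class ContinuousOutcomeModel:
    """Cell means on the endpoint scale for a continuous outcome.

    Cells are named by the classification of the patient: true positive
    (diseased, test +), false negative (diseased, test -), false positive
    (non-diseased, test +) and true negative (non-diseased, test -).
    ``sd`` is the common within-cell standard deviation.
    """

    mean_tp: float
    mean_fn: float
    mean_fp: float
    mean_tn: float
    sd: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValidationError(f"sd must be positive, got {self.sd!r}")


OutcomeModel = Union[BinaryOutcomeModel, ContinuousOutcomeModel]


@dataclass(frozen=True)
class ManagementRule:
    """Deterministic result-to-management mapping: m(+) = I, m(-) = II."""

    positive: str = "I"
    negative: str = "II"

    def __post_init__(self) -> None:
        if (self.positive, self.negative) != ("I", "II"):
            raise ValidationError(
                "only the canonical rule m(+)=I, m(-)=II is supported"
            )

    def management(self, result_positive: bool) -> str:
        return self.positive if result_positive else self.negative


@dataclass(frozen=True)
class DesignParams:
    """Frequentist design parameters of the balanced (1:1) trial."""

    alpha: float = 0.05
    power: float = 0.80
    interim_fraction: float = 0.5

    def __post_init__(self) -> None:
        _check_prob(self.alpha, "alpha", open_interval=True)
        _check_prob(self.power, "power", open_interval=True)
        _check_prob(self.interim_fraction, "interim_fraction", open_interval=True)


@dataclass(frozen=True)
class ScenarioSpec:
    """One complete simulated world.

    ``pi_true`` drives data generation; ``pi_assumed`` is what the planners
    believed.  ``acc_A``/``acc_B`` are the alternative-hypothesis accuracies
    of the two tests and are always the values used in sample-size
    computations.  Under ``hypothesis='null'`` the *data* are generated with
    test A's accuracy in both arms (so the arm outcome distributions are
    identical) while planning and recalculation still use the alternative
    accuracies, mirroring how a trial is sized for the effect it hopes to
    detect and then evaluated under no effect.

    ``planning_delta`` optionally overrides the model-implied effect in the
    planning-stage calculation for continuous endpoints (e.g. planning with
    a rounded clinically-stated difference).
    """

    pi_true: float
    pi_assumed: float
    acc_A: TestAccuracy
    acc_B: TestAccuracy
    outcomes: OutcomeModel
    design: DesignParams = field(default_factory=DesignParams)
    hypothesis: str = "alternative"
    management: ManagementRule = field(default_factory=ManagementRule)
    planning_delta: float | None = None

    def __post_init__(self) -> None:
        _check_prob(self.pi_true, "pi_true", open_interval=True)
        _check_prob(self.pi_assumed, "pi_assumed", open_interval=True)
        if self.hypothesis not in ("alternative", "null"):
            raise ValidationError(
                f"hypothesis must be 'alternative' or 'null', got {self.hypothesis!r}"
            )

    @property
    def is_binary(self) -> bool:
        return isinstance(self.outcomes, BinaryOutcomeModel)

    def generating_accuracies(self) -> tuple[TestAccuracy, TestAccuracy]:
        """Accuracies used to generate data (A, B).

        Under the null hypothesis both arms apply a test with A's accuracy,
        which forces the two arm outcome distributions to coincide while
        leaving the subgroup outcome parameters at their alternative values.
        """
        if self.hypothesis == "null":
            return self.acc_A, self.acc_A
        return self.acc_A, self.acc_B

    def arm_rates(self, pi: float) -> tuple[float, float]:
        """Planning-stage expected outcomes (theta_A, theta_B) at prevalence pi."""
        if self.is_binary:
            return (
                expected_event_rate(pi, self.acc_A, self.outcomes),
                expected_event_rate(pi, self.acc_B, self.outcomes),
            )
        return (
            expected_mean_response(pi, self.acc_A, self.outcomes),
            expected_mean_response(pi, self.acc_B, self.outcomes),
        )

    def generating_rates(self, pi: float | None = None) -> tuple[float, float]:
        """Expected outcomes of the data-generating arms at prevalence pi
        (defaults to ``pi_true``)."""
        if pi is None:
            pi = self.pi_true
        gen_a, gen_b = self.generating_accuracies()
        if self.is_binary:
            return (
                expected_event_rate(pi, gen_a, self.outcomes),
                expected_event_rate(pi, gen_b, self.outcomes),
            )
        return (
            expected_mean_response(pi, gen_a, self.outcomes),
            expected_mean_response(pi, gen_b, self.outcomes),
        )

    def null_twin(self) -> "ScenarioSpec":
        """The matched no-effect scenario (same parameters, null hypothesis)."""
        return replace(self, hypothesis="null")


def expected_event_rate(pi, acc: TestAccuracy, outcomes: BinaryOutcomeModel):
    """Expected event rate theta of one test-treatment arm (binary endpoint).

    Mixes the four management-by-disease event probabilities over the joint
    law of disease status and test result.  Accepts a scalar or array
    prevalence; the result is exactly linear in ``pi``.
    """
    if not isinstance(outcomes, BinaryOutcomeModel):
        raise ValidationError("expected_event_rate requires a BinaryOutcomeModel")
    _check_prob(pi, "pi")
    pi = np.asarray(pi, dtype=float)
    diseased = acc.se * outcomes.mu_I_pos + (1.0 - acc.se) * outcomes.mu_II_pos
    healthy = (1.0 - acc.sp) * outcomes.mu_I_neg + acc.sp * outcomes.mu_II_neg
    theta = pi * diseased + (1.0 - pi) * healthy
    return float(theta) if theta.ndim == 0 else theta


def expected_mean_response(pi, acc: TestAccuracy, outcomes: ContinuousOutcomeModel):
    """Expected mean response of one arm for a continuous endpoint.

    Same mixture as :func:`expected_event_rate` with the cell means of the
    classification cells (TP routed to management I, FN to II, FP to I,
    TN to II).
    """
    if not isinstance(outcomes, ContinuousOutcomeModel):
        raise ValidationError("expected_mean_response requires a ContinuousOutcomeModel")
    _check_prob(pi, "pi")
    pi = np.asarray(pi, dtype=float)
    diseased = acc.se * outcomes.mean_tp + (1.0 - acc.se) * outcomes.mean_fn
    healthy = (1.0 - acc.sp) * outcomes.mean_fp + acc.sp * outcomes.mean_tn
    value = pi * diseased + (1.0 - pi) * healthy
    return float(value) if value.ndim == 0 else value


def effect_size(scenario: ScenarioSpec, use_pi: float) -> float:
    """Arm difference Delta = theta_A - theta_B evaluated at prevalence ``use_pi``.

    Uses the alternative-hypothesis (planning) accuracies; antisymmetric
    under swapping the arms.
    """
    theta_a, theta_b = scenario.arm_rates(use_pi)
    return theta_a - theta_b


def pooled_rate(theta_A: float, theta_B: float) -> float:
    """Overall response rate of the balanced design, (theta_A + theta_B) / 2."""
    _check_prob(theta_A, "theta_A")
    _check_prob(theta_B, "theta_B")
    return 0.5 * (theta_A + theta_B)
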