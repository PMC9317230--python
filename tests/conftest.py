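import numpy as np
import pytest

from testtreat import (
    BinaryOutcomeModel,
    ContinuousOutcomeModel,
    DesignParams,
    ScenarioSpec,
    TestAccuracy,
)


@pytest.fixture
def gain_scenario() -> ScenarioSpec:
    """Binary scenario in which recalculation pays off: prevalence assumed
    0.2 but truly 0.4, test A clearly more accurate than test B."""
    return ScenarioSpec(
        pi_true=0.4,
        pi_assumed=0.2,
        acc_A=TestAccuracy(se=0.95, sp=0.90),
        acc_B=TestAccuracy(se=0.70, sp=0.75),
        outcomes=BinaryOutcomeModel(
            mu_I_pos=0.1, mu_II_pos=0.25, mu_I_neg=0.2, mu_II_neg=0.05
        ),
        design=DesignParams(alpha=0.05, power=0.8, interim_fraction=0.5),
    )


@pytest.fixture
def tb_scenario() -> ScenarioSpec:
    """Continuous-endpoint tuberculosis follow-up scenario: TBscore cell
    means TP=2, FN=5, FP=4, TN=1 (SD 2), molecular test 0.88/0.98 versus
    microscopy 0.50/0.965, prevalence 15%, planned on the rounded effect 0.2."""
    return ScenarioSpec(
        pi_true=0.15,
        pi_assumed=0.15,
        acc_A=TestAccuracy(se=0.88, sp=0.98),
        acc_B=TestAccuracy(se=0.50, sp=0.965),
        outcomes=ContinuousOutcomeModel(mean_tp=2, mean_fn=5, mean_fp=4, mean_tn=1, sd=2),
        design=DesignParams(alpha=0.05, power=0.8, interim_fraction=0.5),
        planning_delta=0.2,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)
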