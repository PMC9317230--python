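"""Three-step blinded recalculation and the prevalence estimators."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from testtreat import (
    BinaryOutcomeModel,
    EmptyInterimError,
    InterimSnapshot,
    ScenarioSpec,
    TestAccuracy,
    UninformativeTestsError,
    ValidationError,
    estimate_prevalence_mle,
    interim_size,
    invert_positive_rate,
    prevalence_from_positive_rate,
    recalculate,
    required_size,
)


def forward_positive_rate(pi, acc_a, acc_b):
    """The forward map: summed positive probability of both tests."""
    return (
        pi * acc_a.se + (1 - pi) * (1 - acc_a.sp)
        + pi * acc_b.se + (1 - pi) * (1 - acc_b.sp)
    )


class TestInterimSize:
    @pytest.mark.parametrize(
        "n0, f, expected",
        [
            (3142, 0.5, 1572),  # ceil gives odd 1571, rounded up to even
            (100, 0.5, 50),
            (101, 0.5, 52),
            (3804, 0.5, 1902),
        ],
    )
    def test_even_rounding(self, n0, f, expected):
        n1 = interim_size(n0, f)
        assert n1 == expected
        assert n1 % 2 == 0

    def test_invalid_fraction(self):
        for f in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValidationError):
                interim_size(100, f)


class TestPrevalenceMLE:
    def test_simple_fraction(self):
        assert estimate_prevalence_mle(InterimSnapshot(n1=100, n_pos_ref=25)) == 0.25
        assert estimate_prevalence_mle(InterimSnapshot(n1=50, n_pos_ref=0)) == 0.0

    def test_empty_interim(self):
        with pytest.raises(EmptyInterimError):
            estimate_prevalence_mle(InterimSnapshot(n1=0, n_pos_ref=0))

    def test_unbiased_under_binomial_sampling(self, rng):
        n1, pi = 1902, 0.4
        draws = rng.binomial(n1, pi, size=10_000) / n1
        mc_se = np.sqrt(pi * (1 - pi) / n1 / 10_000)
        assert abs(draws.mean() - pi) < 4 * mc_se

    def test_snapshot_validation(self):
        with pytest.raises(ValidationError):
            InterimSnapshot(n1=10, n_pos_ref=11)


class TestPositiveRateInversion:
    def test_perfect_tests(self):
        acc = TestAccuracy(1.0, 1.0)
        assert prevalence_from_positive_rate(0.3, acc, acc) == pytest.approx(0.3)

    def test_tb_tests_roundtrip(self):
        acc_a, acc_b = TestAccuracy(0.88, 0.98), TestAccuracy(0.50, 0.965)
        p_plus = forward_positive_rate(0.15, acc_a, acc_b)
        assert p_plus == pytest.approx(0.25375, abs=1e-12)
        assert invert_positive_rate(p_plus, acc_a, acc_b) == pytest.approx(0.15, abs=1e-12)

    def test_uninformative_tests(self):
        coin = TestAccuracy(0.5, 0.5)
        with pytest.raises(UninformativeTestsError):
            invert_positive_rate(0.7, coin, coin)

    def test_unattainable_rate_rejected(self):
        acc_a, acc_b = TestAccuracy(0.9, 0.95), TestAccuracy(0.8, 0.9)
        with pytest.raises(ValidationError):
            invert_positive_rate(1.8, acc_a, acc_b)  # above Se_A + Se_B
        with pytest.raises(ValidationError):
            invert_positive_rate(0.05, acc_a, acc_b)  # below (1-Sp_A)+(1-Sp_B)

    def test_roundtrip_identity_random_draws(self):
        rng = np.random.default_rng(7)
        count = 0
        while count < 1000:
            pi = rng.uniform(0.01, 0.99)
            acc_a = TestAccuracy(rng.uniform(0.5, 1.0), rng.uniform(0.5, 1.0))
            acc_b = TestAccuracy(rng.uniform(0.5, 1.0), rng.uniform(0.5, 1.0))
            if abs(acc_a.youden + acc_b.youden) < 1e-6:
                continue
            p_plus = forward_positive_rate(pi, acc_a, acc_b)
            assert invert_positive_rate(p_plus, acc_a, acc_b) == pytest.approx(
                pi, abs=1e-12
            )
            count += 1

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        pi=st.floats(0.001, 0.999),
        se_a=st.floats(0.55, 1.0),
        sp_a=st.floats(0.55, 1.0),
        se_b=st.floats(0.55, 1.0),
        sp_b=st.floats(0.55, 1.0),
    )
    def test_roundtrip_property(self, pi, se_a, sp_a, se_b, sp_b):
        acc_a, acc_b = TestAccuracy(se_a, sp_a), TestAccuracy(se_b, sp_b)
        p_plus = forward_positive_rate(pi, acc_a, acc_b)
        assert invert_positive_rate(p_plus, acc_a, acc_b) == pytest.approx(pi, abs=1e-9)


class TestRecalculate:
    def test_true_prevalence_reproduces_required_size(self, gain_scenario):
        result = recalculate(gain_scenario, pi_hat=0.4, n1=1902)
        assert result.n_star == required_size(gain_scenario).n_total == 3360
        assert result.n_final == 3360
        assert not result.capped

    def test_confirmed_assumption_keeps_initial_size(self, gain_scenario):
        result = recalculate(gain_scenario, pi_hat=gain_scenario.pi_assumed, n1=1902)
        assert result.n_star == result.n0 == 3804
        assert result.n_final == 3804

    def test_small_recalculated_size_floors_at_interim(self, gain_scenario):
        # at high prevalence the effect grows, N* = 2520 < the pilot of 2600
        result = recalculate(gain_scenario, pi_hat=0.95, n1=2600)
        assert result.n_star == 2520
        assert result.n_final == 2600

    def test_degenerate_estimate_is_capped_and_flagged(self):
        # effect changes sign at pi = 0.4 for these accuracy pairs
        crossing = ScenarioSpec(
            pi_true=0.2,
            pi_assumed=0.2,
            acc_A=TestAccuracy(0.95, 0.80),
            acc_B=TestAccuracy(0.80, 0.90),
            outcomes=BinaryOutcomeModel(
                mu_I_pos=0.1, mu_II_pos=0.25, mu_I_neg=0.2, mu_II_neg=0.05
            ),
        )
        result = recalculate(crossing, pi_hat=0.4, n1=500)
        assert result.capped
        assert result.n_star == 10 * result.n0
        assert result.n_final == max(500, result.n_star)

    def test_final_size_never_below_interim(self, gain_scenario):
        for pi_hat in (0.05, 0.2, 0.4, 0.6, 0.9):
            result = recalculate(gain_scenario, pi_hat=pi_hat, n1=1902)
            assert result.n_final >= 1902
            if result.n_star >= 1902:
                assert result.n_final == result.n_star
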