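"""Single-replication simulators and the Wald analysis."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from testtreat import (
    ScenarioSpec,
    TestAccuracy,
    BinaryOutcomeModel,
    ValidationError,
    counts_from_patients,
    expected_event_rate,
    read_patient_table,
    run_adaptive_replication,
    run_fixed_replication,
    simulate_cohort,
    simulate_patients,
    snapshot_from_patients,
    wald_two_proportions,
    write_patient_table,
)


class TestWald:
    def test_hand_computed_example(self):
        res = wald_two_proportions(30, 100, 50, 100)
        assert res.z == pytest.approx(-2.949, abs=1e-3)
        assert res.p_value == pytest.approx(0.00319, abs=1e-5)
        assert not res.degenerate

    def test_equal_rates_give_zero_statistic(self):
        res = wald_two_proportions(17, 80, 17, 80)
        assert (res.z, res.p_value) == (0.0, 1.0)

    def test_zero_variance_flagged(self):
        res = wald_two_proportions(0, 50, 0, 50)
        assert res == (0.0, 1.0, True)
        assert wald_two_proportions(50, 50, 50, 50).degenerate

    def test_antisymmetric_in_arms(self):
        a = wald_two_proportions(12, 90, 31, 110)
        b = wald_two_proportions(31, 110, 12, 90)
        assert a.z == pytest.approx(-b.z)
        assert a.p_value == pytest.approx(b.p_value)

    def test_count_validation(self):
        with pytest.raises(ValidationError):
            wald_two_proportions(5, 0, 1, 10)
        with pytest.raises(ValidationError):
            wald_two_proportions(11, 10, 1, 10)


class TestGenerativeChain:
    def test_accurate_test_routes_diseased_to_management_I(self, rng):
        scenario = ScenarioSpec(
            pi_true=0.9,
            pi_assumed=0.9,
            acc_A=TestAccuracy(1.0, 1.0),
            acc_B=TestAccuracy(1.0, 1.0),
            outcomes=BinaryOutcomeModel(
                mu_I_pos=0.1, mu_II_pos=0.25, mu_I_neg=0.2, mu_II_neg=0.05
            ),
        )
        table = simulate_patients(400, scenario, rng)
        diseased = table[table.D == 1]
        assert (diseased.R == 1).all() and (diseased.M == "I").all()
        healthy = table[table.D == 0]
        assert (healthy.R == 0).all() and (healthy.M == "II").all()

    def test_outcome_independent_of_path_when_mus_equal(self, gain_scenario, rng):
        flat = dataclasses.replace(
            gain_scenario,
            outcomes=BinaryOutcomeModel(
                mu_I_pos=0.3, mu_II_pos=0.3, mu_I_neg=0.3, mu_II_neg=0.3
            ),
        )
        n, reps = 500, 400
        events = np.array(
            [simulate_cohort(n, flat, rng).x_cells.sum() for _ in range(reps)]
        )
        se = np.sqrt(0.3 * 0.7 / n / reps)
        assert abs(events.mean() / n - 0.3) < 4 * se

    def test_event_rate_matches_model_expectation(self, gain_scenario, rng):
        # cross-module oracle: empirical arm-A event fraction vs theta_A
        theta_a = expected_event_rate(0.4, gain_scenario.acc_A, gain_scenario.outcomes)
        n, reps = 3360, 300
        fractions = np.array(
            [
                simulate_cohort(n, gain_scenario, rng).events("A") / (n // 2)
                for _ in range(reps)
            ]
        )
        se = np.sqrt(theta_a * (1 - theta_a) / (n // 2) / reps)
        assert abs(fractions.mean() - theta_a) < 4 * se

    def test_odd_cohort_rejected(self, gain_scenario, rng):
        with pytest.raises(ValidationError):
            simulate_cohort(101, gain_scenario, rng)

    def test_aggregated_and_per_patient_engines_agree(self, gain_scenario):
        """Chi-square homogeneity of pooled (arm x result x disease) cell
        counts from the two engines."""
        n, reps = 200, 300
        rng_a = np.random.default_rng(3)
        rng_b = np.random.default_rng(4)
        agg = np.zeros((2, 2, 2))
        pat = np.zeros((2, 2, 2))
        for _ in range(reps):
            agg += simulate_cohort(n, gain_scenario, rng_a).n_cells
            pat += counts_from_patients(simulate_patients(n, gain_scenario, rng_b)).n_cells
        table = np.vstack([agg.ravel(), pat.ravel()])
        _, p, _, _ = stats.chi2_contingency(table)
        assert p > 0.01


class TestReplications:
    def test_adaptive_bookkeeping(self, gain_scenario, rng):
        rep = run_adaptive_replication(gain_scenario, rng)
        assert rep.n0 == 3804 and rep.n1 == 1902
        assert rep.n_final == max(rep.n1, rep.n_star) == rep.counts.n_total
        assert rep.pi_hat == pytest.approx(0.4, abs=0.05)
        assert rep.reject == (rep.p_value < 0.05)

    def test_fixed_design_recruits_planned_size(self, gain_scenario, rng):
        for _ in range(3):
            rep = run_fixed_replication(gain_scenario, rng)
            assert rep.n_final == rep.n0 == 3804
            assert rep.n1 is None and rep.pi_hat is None

    def test_same_seed_bitwise_identical(self, gain_scenario):
        rep1 = run_adaptive_replication(gain_scenario, np.random.default_rng(5))
        rep2 = run_adaptive_replication(gain_scenario, np.random.default_rng(5))
        assert rep1.z == rep2.z and rep1.n_final == rep2.n_final
        assert (rep1.counts.n_cells == rep2.counts.n_cells).all()
        assert (rep1.counts.x_cells == rep2.counts.x_cells).all()

    def test_null_scenario_rejects_at_alpha(self, gain_scenario):
        twin = gain_scenario.null_twin()
        small = dataclasses.replace(
            twin, pi_assumed=0.4
        )  # keep the replications light: planned size 3360
        rng = np.random.default_rng(8)
        rejections = sum(
            run_fixed_replication(small, rng).reject for _ in range(200)
        )
        # 200 reps: 3.5 MC SDs around 5% -> [0, 16] rejections
        assert rejections <= 16


class TestPatientTables:
    def test_roundtrip_and_snapshot(self, gain_scenario, rng, tmp_path):
        table = simulate_patients(300, gain_scenario, rng)
        path = tmp_path / "patients.csv"
        write_patient_table(table, path)
        back = read_patient_table(path)
        assert (back == table).all().all()
        snap = snapshot_from_patients(back)
        assert snap.n1 == 300
        assert snap.n_pos_ref == table.D.sum()
        assert snap.p_obs == pytest.approx(table.R.mean())

    def test_counts_match_table_margins(self, gain_scenario, rng):
        table = simulate_patients(300, gain_scenario, rng)
        counts = counts_from_patients(table)
        assert counts.n_total == 300
        assert counts.n_arm("A") == 150
        assert counts.events("B") == table[table.arm == "B"].Y.sum()
        assert counts.n_diseased == table.D.sum()
        assert counts.n_test_positive == table.R.sum()

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("id,arm,D\n1,A,0\n")
        with pytest.raises(ValidationError):
            read_patient_table(path)
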