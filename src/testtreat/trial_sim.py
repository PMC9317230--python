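"""Single-replication simulation of test-treatment trials (binary endpoint).

The generative chain per patient is: disease D ~ Bernoulli(pi); arm by 1:1
allocation; test result R | D from the arm's sensitivity/specificity;
management M = m(R) (positives to I, negatives to II); outcome
Y ~ Bernoulli(mu_{M,D}).

Two equivalent engines exist:

* an aggregated engine that draws binomial counts per (arm x disease x
  result) cell — the default, fast enough for millions of replications;
* a per-patient generator used for fixtures and as an oracle in tests.

The final analysis is the unpooled Wald z-test for two independent binomial
proportions on all recruited patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .blinded_recalc import interim_size, recalculate
from .design_model import ScenarioSpec, TestAccuracy, BinaryOutcomeModel
from .errors import ValidationError
from .sample_size import planned_size

__all__ = [
    "ArmCounts",
    "WaldResult",
    "ReplicationResult",
    "simulate_cohort",
    "simulate_patients",
    "counts_from_patients",
    "wald_two_proportions",
    "run_adaptive_replication",
    "run_fixed_replication",
    "write_patient_table",
    "read_patient_table",
    "snapshot_from_patients",
]

ARMS = ("A", "B")
_PATIENT_COLUMNS = ["id", "arm", "D", "R", "M", "Y"]


@dataclass
class ArmCounts:
    """Aggregated sufficient statistics of one simulated cohort.

    ``n_cells``/``x_cells`` have shape (2 arms, 2 results, 2 disease states)
    with index order arm (A=0, B=1), result (+=0, -=1), disease (+=0, -=1);
    ``x`` counts outcome events within the cell.
    """

    n_cells: np.ndarray = field(default_factory=lambda: np.zeros((2, 2, 2), dtype=np.int64))
    x_cells: np.ndarray = field(default_factory=lambda: np.zeros((2, 2, 2), dtype=np.int64))

    def __add__(self, other: "ArmCounts") -> "ArmCounts":
        return ArmCounts(self.n_cells + other.n_cells, self.x_cells + other.x_cells)

    def n_arm(self, arm: str) -> int:
        return int(self.n_cells[ARMS.index(arm)].sum())

    def events(self, arm: str) -> int:
        return int(self.x_cells[ARMS.index(arm)].sum())

    @property
    def n_total(self) -> int:
        return int(self.n_cells.sum())

    @property
    def n_diseased(self) -> int:
        """Reference-standard positives (both arms pooled)."""
        return int(self.n_cells[:, :, 0].sum())

    @property
    def n_test_positive(self) -> int:
        return int(self.n_cells[:, 0, :].sum())


def _sample_arm_cells(
    rng: np.random.Generator,
    n_arm: int,
    pi: float,
    acc: TestAccuracy,
    outcomes: BinaryOutcomeModel,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (n, x) 2x2 cell arrays (result x disease) for one arm."""
    d = rng.binomial(n_arm, pi)
    tp = rng.binomial(d, acc.se)          # diseased, test +
    fp = rng.binomial(n_arm - d, 1.0 - acc.sp)  # healthy, test +
    n = np.array([[tp, fp], [d - tp, n_arm - d - fp]], dtype=np.int64)
    x = np.array(
        [
            [rng.binomial(tp, outcomes.mu_I_pos), rng.binomial(fp, outcomes.mu_I_neg)],
            [
                rng.binomial(d - tp, outcomes.mu_II_pos),
                rng.binomial(n_arm - d - fp, outcomes.mu_II_neg),
            ],
        ],
        dtype=np.int64,
    )
    return n, x


def simulate_cohort(n: int, scenario: ScenarioSpec, rng: np.random.Generator) -> ArmCounts:
    """Simulate ``n`` patients (n/2 per arm) with the aggregated cell engine."""
    if n % 2:
        raise ValidationError("cohort size must be even under 1:1 allocation")
    if not scenario.is_binary:
        raise ValidationError("simulation covers binary endpoints only")
    counts = ArmCounts()
    for idx, acc in enumerate(scenario.generating_accuracies()):
        n_cell, x_cell = _sample_arm_cells(
            rng, n // 2, scenario.pi_true, acc, scenario.outcomes
        )
        counts.n_cells[idx] = n_cell
        counts.x_cells[idx] = x_cell
    return counts


def simulate_patients(n: int, scenario: ScenarioSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Per-patient generator: one row per patient with columns
    id, arm ('A'/'B'), D, R, Y (0/1) and M ('I'/'II')."""
    if n % 2:
        raise ValidationError("cohort size must be even under 1:1 allocation")
    if not scenario.is_binary:
        raise ValidationError("simulation covers binary endpoints only")
    half = n // 2
    arms = np.repeat(["A", "B"], half)
    acc_a, acc_b = scenario.generating_accuracies()
    d = rng.random(n) < scenario.pi_true
    p_pos = np.where(
        arms == "A",
        np.where(d, acc_a.se, 1.0 - acc_a.sp),
        np.where(d, acc_b.se, 1.0 - acc_b.sp),
    )
    r = rng.random(n) < p_pos
    mu = scenario.outcomes
    p_event = np.where(
        r,
        np.where(d, mu.mu_I_pos, mu.mu_I_neg),
        np.where(d, mu.mu_II_pos, mu.mu_II_neg),
    )
    y = rng.random(n) < p_event
    return pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "arm": arms,
            "D": d.astype(int),
            "R": r.astype(int),
            "M": np.where(r, "I", "II"),
            "Y": y.astype(int),
        }
    )


def counts_from_patients(table: pd.DataFrame) -> ArmCounts:
    """Aggregate a patient-level table into :class:`ArmCounts`."""
    counts = ArmCounts()
    for (arm, r, d), group in table.groupby(["arm", "R", "D"]):
        i, j, k = ARMS.index(arm), 1 - int(r), 1 - int(d)
        counts.n_cells[i, j, k] = len(group)
        counts.x_cells[i, j, k] = int(group["Y"].sum())
    return counts


def snapshot_from_patients(table: pd.DataFrame):
    """Blinded interim snapshot (size, reference-standard positives, pooled
    positive rate) from a patient-level table."""
    from .blinded_recalc import InterimSnapshot

    return InterimSnapshot(
        n1=len(table),
        n_pos_ref=int(table["D"].sum()),
        p_obs=float(table["R"].mean()) if len(table) else None,
    )


class WaldResult(NamedTuple):
    z: float
    p_value: float
    degenerate: bool = False


def wald_two_proportions(x_A: int, n_A: int, x_B: int, n_B: int) -> WaldResult:
    """Unpooled Wald z-test for two independent binomial proportions.

    z = (pA - pB) / sqrt(pA(1-pA)/nA + pB(1-pB)/nB), two-sided p from the
    standard normal.  If both sample proportions are degenerate (variance
    estimate zero) the test cannot reject: returns z=0, p=1, flagged.
    """
    if n_A < 1 or n_B < 1:
        raise ValidationError("both arms need at least one patient")
    if not (0 <= x_A <= n_A and 0 <= x_B <= n_B):
        raise ValidationError("event counts must lie in [0, n]")
    p_a, p_b = x_A / n_A, x_B / n_B
    var = p_a * (1.0 - p_a) / n_A + p_b * (1.0 - p_b) / n_B
    if var == 0.0:
        return WaldResult(z=0.0, p_value=1.0, degenerate=True)
    z = (p_a - p_b) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return WaldResult(z=float(z), p_value=float(p), degenerate=False)


@dataclass(frozen=True)
class ReplicationResult:
    """One simulated trial: design bookkeeping plus the final Wald test."""

    design_kind: str
    n0: int
    n1: int | None
    pi_hat: float | None
    n_star: int | None
    n_final: int
    counts: ArmCounts
    z: float
    p_value: float
    reject: bool
    capped: bool = False

    def __post_init__(self) -> None:
        if self.design_kind not in ("adaptive", "fixed"):
            raise ValidationError("design_kind must be 'adaptive' or 'fixed'")


def _finalize(scenario, design_kind, n0, n1, pi_hat, n_star, counts, capped=False):
    test = wald_two_proportions(
        counts.events("A"), counts.n_arm("A"), counts.events("B"), counts.n_arm("B")
    )
    return ReplicationResult(
        design_kind=design_kind,
        n0=n0,
        n1=n1,
        pi_hat=pi_hat,
        n_star=n_star,
        n_final=counts.n_total,
        counts=counts,
        z=test.z,
        p_value=test.p_value,
        reject=test.p_value < scenario.design.alpha,
        capped=capped,
    )


def run_adaptive_replication(
    scenario: ScenarioSpec,
    rng: np.random.Generator,
    n_max: int | None = None,
) -> ReplicationResult:
    """One adaptive trial: plan, recruit the pilot, blindly re-estimate the
    prevalence from reference-standard statuses, recalculate, finish, test.

    Only the pooled count of reference-standard positives leaves the interim
    data — outcomes and arm labels never feed the recalculation.
    """
    n0 = planned_size(scenario).n_total
    n1 = interim_size(n0, scenario.design.interim_fraction)
    pilot = simulate_cohort(n1, scenario, rng)
    pi_hat = pilot.n_diseased / n1
    recalc = recalculate(scenario, pi_hat, n1, n_max=n_max)
    counts = pilot
    n_extra = recalc.n_final - n1
    if n_extra > 0:
        counts = counts + simulate_cohort(n_extra, scenario, rng)
    return _finalize(
        scenario, "adaptive", n0, n1, pi_hat, recalc.n_star, counts, recalc.capped
    )


def run_fixed_replication(scenario: ScenarioSpec, rng: np.random.Generator) -> ReplicationResult:
    """One fixed-design trial: recruit the planned N0 and test once."""
    n0 = planned_size(scenario).n_total
    counts = simulate_cohort(n0, scenario, rng)
    return _finalize(scenario, "fixed", n0, None, None, None, counts)


def write_patient_table(table: pd.DataFrame, path) -> None:
    """Write a patient-level table as comma-separated text (header row;
    D/R/Y coded 0/1, arm as A/B, management as I/II)."""
    table.to_csv(path, index=False, columns=_PATIENT_COLUMNS)


def read_patient_table(path) -> pd.DataFrame:
    """Read a table written by :func:`write_patient_table`."""
    table = pd.read_csv(path)
    missing = set(_PATIENT_COLUMNS) - set(table.columns)
    if missing:
        raise ValidationError(f"patient table missing columns: {sorted(missing)}")
    return table[_PATIENT_COLUMNS]
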