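"""Blinded sample size recalculation at the interim analysis.

Uses the binary-endpoint scenario in which the planners assumed a 20%
prevalence but 40% of the interim patients are reference-standard positive.
The recalculation looks only at the pooled count of diseased patients —
never at outcomes or arm labels — so the trial stays blinded and the final
test keeps its unadjusted significance level.
"""

from pathlib import Path

from testtreat import (
    InterimSnapshot,
    estimate_prevalence_mle,
    interim_size,
    load_scenario,
    planned_size,
    prevalence_from_positive_rate,
    recalculate,
    required_size,
)

scenario = load_scenario(Path(__file__).parent / "scenarios" / "recalc_gain.yaml")

n0 = planned_size(scenario).n_total
n1 = interim_size(n0, scenario.design.interim_fraction)
print(f"planned size N0 (at assumed prevalence 0.2): {n0}")
print(f"internal pilot size N1 (50% of N0):          {n1}")

# reference-standard path: 761 of the 1902 pilot patients are truly diseased
snapshot = InterimSnapshot(n1=n1, n_pos_ref=761)
pi_hat = estimate_prevalence_mle(snapshot)
result = recalculate(scenario, pi_hat, n1)
print(f"interim prevalence estimate:                 {pi_hat:.4f}")
print(f"recalculated size N*:                        {result.n_star}")
print(f"final size max(N1, N*):                      {result.n_final}")
print(f"true necessary size (at prevalence 0.4):     {required_size(scenario).n_total}")

# alternative estimator when no reference standard exists: invert the
# pooled positive rate using the (assumed known) test accuracies
pi_from_rate = prevalence_from_positive_rate(0.3675, scenario.acc_A, scenario.acc_B)
print(f"prevalence from a pooled positive rate 0.3675: {pi_from_rate:.4f}")
print()
print(
    "The pilot reveals the prevalence was underestimated; recruiting to the "
    "recalculated size instead of the planned 3804 brings the trial close to "
    "the size it truly needs."
)
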