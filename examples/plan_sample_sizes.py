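"""Plan a test-treatment trial: expected outcomes, effect and sample size.

Loads the continuous-endpoint tuberculosis follow-up scenario (TBscore
cell means TP=2, FN=5, FP=4, TN=1, SD=2; a molecular test with Se/Sp
0.88/0.98 versus microscopy with 0.50/0.965 at 15% prevalence), evaluates
the expected-outcome model and computes the required sample size with the
iterative t-based two-mean formula.
"""

from pathlib import Path

from testtreat import effect_size, load_scenario, planned_size

scenario = load_scenario(Path(__file__).parent / "scenarios" / "tb_follow_up.yaml")

theta_a, theta_b = scenario.arm_rates(scenario.pi_assumed)
delta = effect_size(scenario, scenario.pi_assumed)
plan = planned_size(scenario)

print(f"expected TBscore, arm A (molecular):  {theta_a:.5f}")
print(f"expected TBscore, arm B (microscopy): {theta_b:.5f}")
print(f"model-implied difference:             {delta:.5f}")
print(f"planning difference (rounded):        {scenario.planning_delta}")
print(f"required patients per arm:            {plan.n_per_arm}")
print(f"required patients in total:           {plan.n_total}")
print()
print(
    "A lower TBscore means less morbidity: the more sensitive molecular test "
    f"is expected to reduce the score by {-delta:.2f} points, and detecting a "
    f"0.2-point reduction at 80% power needs {plan.n_total} patients."
)
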