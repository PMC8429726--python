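"""Train the deep double Q-learning dosing agent on the nominal patient.

The agent sees only the day index and a 10-day window of relative
bone-marrow totals, never the rate constants.  This demo uses the reduced
single-CPU budget with two runs; the full protocol uses five runs of up to
50000 resets.
"""

from chemosched import (
    default_config,
    load_tissue,
    nominal_patient,
    reduced_budget_config,
    solve,
)
from chemosched.ddqn import best_of_runs

nominal = nominal_patient()
cfg = reduced_budget_config(seed=0, runs=2)

policy, summary = best_of_runs(nominal, cfg)
print(summary.to_string(index=False))

optimum = solve(load_tissue("bone_marrow"), default_config()).value
print(f"\nbest greedy score {policy.nominal_score:.4f} vs exact optimum {optimum:.4f}")
print(f"-> the selected run reaches {100 * policy.nominal_score / optimum:.1f}% of the "
      "theoretical maximum on the patient it trained on")
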