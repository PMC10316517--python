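"""Scenario-recovery experiment: how reliably does selection find truth?

Simulates all eight scenarios for the mixed community, then repeatedly
draws noisy observation sets from the D2 endpoints (cv 0.2, 6 replicates)
and checks which scenario the staged selection picks.
"""

from aquacosm.recovery import recovery_experiment, simulate_all_scenarios

endpoints = simulate_all_scenarios(3)
result = recovery_experiment(
    truth="D2", set_id=3, cv=0.2, n_reps=6, n_seeds=50, seed=1,
    endpoints=endpoints,
)

print(f"truth: {result.truth} (set {result.set_id}, cv {result.cv}, "
      f"{result.n_reps} replicates, {result.n_seeds} draws)")
print("selections:", dict(sorted(result.selections.items())))
print(f"recovery rate: {result.recovery_rate:.0%}")
print(
    "\nEach draw adds lognormal replicate noise to the D2 endpoint curves "
    "and re-runs the\nfull assessment; the recovery rate is the fraction "
    "of draws in which D2 survives\nboth elimination stages and wins the "
    "periphyton ranking."
)
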