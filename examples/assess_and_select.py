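"""Full pattern-oriented assessment and scenario selection.

Simulates endpoint tables for all eight scenarios (mixed community, set 3),
draws a synthetic observation set from the D2 endpoints (lognormal
replicate noise, cv 0.2, 6 replicates), correlates every scenario's curves
against the observations (48 correlations: 8 scenarios x 3 groups x 2
temperatures) and runs the staged selection.
"""

import pandas as pd

import aquacosm as aq
from aquacosm.recovery import simulate_all_scenarios

endpoints = simulate_all_scenarios(3)
observations = aq.observations_from_simulation(
    endpoints["D2"], cv=0.2, n_reps=6, seed=42
)

correlations = {}
frames = []
for sid, table in endpoints.items():
    entries = aq.response_correlation(table, observations)
    correlations[sid] = entries
    frame = aq.correlation_frame(entries)
    frame.insert(0, "scenario", sid)
    frames.append(frame)

table = pd.concat(frames, ignore_index=True)
print("correlation table (r and significance tier):")
wide = table.pivot_table(
    index="scenario", columns=["group", "temperature"], values="r"
).round(3)
print(wide.to_string())

result = aq.select_scenario(correlations)
print("\nselection audit:")
for line in result.audit:
    print(" ", line)
print(
    f"\nselected scenario: {result.selected} — the generating scenario, "
    "recovered because its\nmacrophyte curves stay significantly correlated "
    "at both temperatures and its\nperiphyton correlations outrank the "
    "other survivors'."
)
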