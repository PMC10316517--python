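"""Effect sizes and community composition from synthetic observations.

Generates the shipped qualitative endpoint pattern (macrophytes depressed
by run-off in the cool chamber, phytoplankton rising with run-off,
periphyton noisy-flat), computes Hedges' g of each run-off level against
the control for macrophytes at 22 degC, and upscales the observations to
whole-microcosm totals and group shares.
"""

import numpy as np

import aquacosm as aq

obs = aq.generate_observations(aq.default_pattern_spec(), seed=7)

print("Hedges' g (run-off level vs control), macrophytes at 22 degC:")
macro = obs[(obs.group == "macrophytes") & (obs.temperature == 22.0)]
control = macro[macro.aro_level == 0]["biomass"].to_numpy()
for level in aq.ARO_LEVELS[1:]:
    treated = macro[macro.aro_level == level]["biomass"].to_numpy()
    g, se = aq.hedges_g(treated, control)
    print(f"  ARO {level:>2}x: g = {g:6.2f} +/- {se:.2f}")

print("\ngroup shares of whole-microcosm biomass (22 degC):")
shares = aq.upscale_to_microcosm(obs, reference=(22.0, 0))
cool = shares[shares.temperature == 22.0]
for level in aq.ARO_LEVELS:
    cell = cool[cool.aro_level == level].set_index("group")
    rel = cell["relative_total"].iloc[0]
    parts = "  ".join(
        f"{grp[:5]} {cell.loc[grp, 'share']:.2f}"
        for grp in ("macrophytes", "periphyton", "phytoplankton")
    )
    print(f"  ARO {level:>2}x: {parts}  (total vs control: {rel:.2f})")

print(
    "\nNegative g marks the macrophyte biomass loss under every run-off "
    "level; the share\ntable shows the periphyton-scaled wall totals "
    "dominating the microcosm and the\nphytoplankton share creeping up "
    "with run-off."
)
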