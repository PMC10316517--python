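"""Compare macrophyte dose-response curves across sensitivity scenarios.

Runs the full 6-level x 2-temperature design for scenarios B1 (macrophytes
most sensitive, temperature-blind) and D2 (microscopic groups initially
most sensitive, temperature-dependent, tolerance developing) and prints
the macrophyte endpoint biomass along the run-off gradient.
"""

import aquacosm as aq

setup = aq.ModelSetup()
for sid in ("B1", "D2"):
    endpoints = aq.run_full_design(sid, 3, setup)
    macro = endpoints[endpoints.group == "macrophytes"]
    print(f"\nscenario {sid}: macrophyte endpoint biomass (mg C)")
    print(f"  {'ARO level':>9}  {'22 degC':>8}  {'26 degC':>8}")
    for level in aq.ARO_LEVELS:
        cool = macro[(macro.aro_level == level) & (macro.temperature == 22.0)]
        warm = macro[(macro.aro_level == level) & (macro.temperature == 26.0)]
        print(f"  {level:>8}x  {cool.biomass.iloc[0]:8.1f}  "
              f"{warm.biomass.iloc[0]:8.1f}")

print(
    "\nUnder B1 macrophytes collapse monotonically with run-off at both "
    "temperatures;\nunder D2 the direct hit is milder (macrophytes are not "
    "the most sensitive group)\nand the warm treatment is buffered further "
    "by the doubled EC50."
)
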