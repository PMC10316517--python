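"""Primary-producer group identifiers and habits.

The model distinguishes five producer groups. Two phytoplankton groups
represent a trait axis of the planktonic community: ``phyto_alpha`` is
fast-growing and herbicide-sensitive, ``phyto_beta`` slow-growing and
herbicide-resistant. Periphyton is the biofilm on the vessel's inner glass
wall, epiphyton the biofilm on macrophyte surfaces, and macrophytes the
rooted submerged plants.
"""

from __future__ import annotations

PHYTO_ALPHA = "phyto_alpha"
PHYTO_BETA = "phyto_beta"
PERIPHYTON = "periphyton"
EPIPHYTON = "epiphyton"
MACROPHYTES = "macrophytes"

ALL_GROUPS: tuple[str, ...] = (
    PHYTO_ALPHA,
    PHYTO_BETA,
    PERIPHYTON,
    EPIPHYTON,
    MACROPHYTES,
)

PHYTO_GROUPS: tuple[str, ...] = (PHYTO_ALPHA, PHYTO_BETA)

#: Benthic groups whose growth is capped by colonizable area.
BENTHIC_GROUPS: tuple[str, ...] = (PERIPHYTON, EPIPHYTON)

#: Groups with microbial generation times; these develop herbicide tolerance
#: under the D scenarios, macrophytes never do.
MICROSCOPIC_GROUPS: tuple[str, ...] = (
    PHYTO_ALPHA,
    PHYTO_BETA,
    PERIPHYTON,
    EPIPHYTON,
)

#: Where each group lives; fixes the unit regime of its biomass pools.
HABITS: dict[str, str] = {
    PHYTO_ALPHA: "planktonic",
    PHYTO_BETA: "planktonic",
    PERIPHYTON: "benthic_wall",
    EPIPHYTON: "benthic_plant",
    MACROPHYTES: "rooted",
}

#: The three assessment groups measured in the experiment (epiphyton is
#: simulated but not part of the assessment currency).
ASSESSMENT_GROUPS: tuple[str, ...] = ("phytoplankton", "periphyton", "macrophytes")


def validate_group(group: str) -> str:
    if group not in ALL_GROUPS:
        raise ValueError(f"unknown producer group: {group!r}")
    return group
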