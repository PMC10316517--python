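"""Sensitivity scenarios, community sets, the factorial design and dosing.

Eight scenarios (A1..D2) combine three axes: which groups are most
herbicide-sensitive (A: all equal except the resistant phytoplankton group
beta; B: macrophytes most sensitive; C: microscopic groups most sensitive;
D: starts as C but the microscopic groups develop tolerance and end up less
sensitive than macrophytes), whether sensitivity is temperature-dependent
(suffix 2: sensitivities are higher in the cool treatment), and whether
tolerance develops over the exposure (prefix D only).

Three community sets fix the phytoplankton composition: set 1 = fast,
sensitive group alpha alone; set 2 = slow, resistant group beta alone;
set 3 = both. The factorial design crosses six run-off levels (control and
1x..16x with enrichment factor 2) with two temperatures (22 and 26 degC)
over a 19-day exposure, with the run-off mixture applied once at t = 0 and
nutrient pulses twice a week.
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, model_validator

from .groups import (
    EPIPHYTON,
    MACROPHYTES,
    PERIPHYTON,
    PHYTO_ALPHA,
    PHYTO_BETA,
)

SCENARIO_IDS = ("A1", "A2", "B1", "B2", "C1", "C2", "D1", "D2")
ARO_LEVELS = (0, 1, 2, 4, 8, 16)
TEMPERATURES = (22.0, 26.0)
EXPOSURE_DAYS = 19.0

#: Nominal constituent concentrations of the 1x run-off mixture (ug L^-1).
ARO_BASE_CONCENTRATIONS = {
    "terbuthylazine": 0.75,
    "pirimicarb": 3.75,
    "tebuconazole": 22.5,
    "copper": 10.5,
    "NO3_N": 2250.0,
}

#: EC50 multipliers (relative to the sensitive anchor) per scenario family.
_ORDERINGS = {
    "A": {PHYTO_ALPHA: 1.0, PERIPHYTON: 1.0, EPIPHYTON: 1.0,
          MACROPHYTES: 1.0, PHYTO_BETA: 20.0},
    "B": {PHYTO_ALPHA: 1.0, PERIPHYTON: 1.0, EPIPHYTON: 1.0,
          MACROPHYTES: 0.25, PHYTO_BETA: 20.0},
    "C": {PHYTO_ALPHA: 0.25, PERIPHYTON: 0.25, EPIPHYTON: 0.25,
          MACROPHYTES: 1.0, PHYTO_BETA: 20.0},
    # D starts from the C ordering; tolerance then raises microscopic EC50s.
    "D": {PHYTO_ALPHA: 0.25, PERIPHYTON: 0.25, EPIPHYTON: 0.25,
          MACROPHYTES: 1.0, PHYTO_BETA: 20.0},
}


class ScenarioConfig(BaseModel):
    """One of the eight sensitivity/temperature/tolerance scenarios."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    id: str
    sensitivity_ordering: dict[str, float]
    temperature_dependent: bool
    tolerance_development: bool

    @model_validator(mode="after")
    def _check(self) -> "ScenarioConfig":
        if self.id not in SCENARIO_IDS:
            raise ValueError(f"unknown scenario id {self.id!r}")
        if self.temperature_dependent != self.id.endswith("2"):
            raise ValueError("temperature_dependent must match the '2' suffix")
        if self.tolerance_development != self.id.startswith("D"):
            raise ValueError("tolerance_development must match the 'D' prefix")
        others = [m for g, m in self.sensitivity_ordering.items() if g != PHYTO_BETA]
        if not all(self.sensitivity_ordering[PHYTO_BETA] > m for m in others):
            raise ValueError("phyto_beta must be strictly least sensitive")
        return self


class CommunitySet(BaseModel):
    """Assumed phytoplankton composition (community sets 1-3)."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    id: int
    present_phyto_groups: tuple[str, ...]

    @model_validator(mode="after")
    def _check(self) -> "CommunitySet":
        expected = {
            1: (PHYTO_ALPHA,),
            2: (PHYTO_BETA,),
            3: (PHYTO_ALPHA, PHYTO_BETA),
        }
        if self.id not in expected:
            raise ValueError(f"community set id must be 1, 2 or 3, got {self.id}")
        if tuple(self.present_phyto_groups) != expected[self.id]:
            raise ValueError(
                f"set {self.id} must contain exactly {expected[self.id]}"
            )
        return self


def community_set(set_id: int) -> CommunitySet:
    groups = {1: (PHYTO_ALPHA,), 2: (PHYTO_BETA,), 3: (PHYTO_ALPHA, PHYTO_BETA)}
    if set_id not in groups:
        raise ValueError(f"community set id must be 1, 2 or 3, got {set_id}")
    return CommunitySet(id=set_id, present_phyto_groups=groups[set_id])


class Treatment(BaseModel):
    """One cell of the factorial design: run-off level x temperature."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    aro_level: int
    temperature: float
    concentrations: dict[str, float]

    @model_validator(mode="after")
    def _check(self) -> "Treatment":
        if self.aro_level not in ARO_LEVELS:
            raise ValueError(f"aro_level must be one of {ARO_LEVELS}")
        if self.temperature not in TEMPERATURES:
            raise ValueError(f"temperature must be one of {TEMPERATURES}")
        if self.aro_level == 0 and any(v != 0 for v in self.concentrations.values()):
            raise ValueError("control treatment must have zero concentrations")
        if any(v < 0 for v in self.concentrations.values()):
            raise ValueError("concentrations must be non-negative")
        return self

    @property
    def herbicide(self) -> float:
        """Nominal terbuthylazine concentration (ug L^-1), the only
        constituent acting on the modelled producers."""
        return self.concentrations["terbuthylazine"]


class DosingEvent(BaseModel):
    """One nutrient pulse: instantaneous additions to the water column."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    time: float  # d
    additions: dict[str, float]  # {"P_d": mg P m^-3, "NO3_N": mg m^-3}

    @model_validator(mode="after")
    def _check(self) -> "DosingEvent":
        if not self.time > 0:
            raise ValueError("dosing time must be strictly positive")
        if any(v < 0 for v in self.additions.values()):
            raise ValueError("additions must be non-negative")
        return self


def nominal_concentrations(aro_level: int) -> dict[str, float]:
    """Nominal constituent concentrations (ug L^-1) at a run-off level.

    The 1x base vector is scaled linearly by the level; the control (level
    0) is all zeros.
    """
    if aro_level not in ARO_LEVELS:
        raise ValueError(f"aro_level must be one of {ARO_LEVELS}, got {aro_level}")
    return {k: v * aro_level for k, v in ARO_BASE_CONCENTRATIONS.items()}


def build_scenario(scenario_id: str) -> ScenarioConfig:
    """Scenario definition (flags + EC50 ordering) for one of A1..D2."""
    if scenario_id not in SCENARIO_IDS:
        raise ValueError(f"unknown scenario id {scenario_id!r}")
    return ScenarioConfig(
        id=scenario_id,
        sensitivity_ordering=dict(_ORDERINGS[scenario_id[0]]),
        temperature_dependent=scenario_id.endswith("2"),
        tolerance_development=scenario_id.startswith("D"),
    )


def treatment_grid() -> list[Treatment]:
    """The 12 design cells, level-major with the cool chamber first."""
    return [
        Treatment(
            aro_level=level,
            temperature=temp,
            concentrations=nominal_concentrations(level),
        )
        for level in ARO_LEVELS
        for temp in TEMPERATURES
    ]


def dosing_schedule(
    duration_d: float = EXPOSURE_DAYS,
    P_per_event: float = 50.0,
    NO3_N_per_event: float = 0.0,
) -> list[DosingEvent]:
    """Twice-weekly nutrient pulses over the exposure.

    Pulses fall on an even twice-weekly grid (days 3, 7, 10, 14, 17, ...)
    truncated to the duration. P additions are in mg P m^-3 of water; the
    nitrate addition is carried for reporting only.
    """
    if not duration_d > 0:
        raise ValueError("duration must be strictly positive")
    days: list[float] = []
    week = 0
    while True:
        for offset in (3.0, 7.0):
            day = 7.0 * week + offset
            if day <= duration_d:
                days.append(day)
        if 7.0 * (week + 1) > duration_d:
            break
        week += 1
    return [
        DosingEvent(time=d, additions={"P_d": P_per_event, "NO3_N": NO3_N_per_event})
        for d in days
    ]
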