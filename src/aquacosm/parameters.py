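"""Physiological and decomposition parameters, with shipped defaults.

All rates are expressed per day at the reference temperature (22 degC) and
scaled by Q10 factors elsewhere. None of the default values below are
measured quantities from the underlying experiment; they are plausible
literature-range choices for temperate freshwater producers, shipped so the
model runs out of the box and overridable through the config layer.
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, model_validator

from .groups import (
    ALL_GROUPS,
    BENTHIC_GROUPS,
    MACROPHYTES,
    PHYTO_ALPHA,
    PHYTO_BETA,
    PHYTO_GROUPS,
)


class GroupParameters(BaseModel):
    """Per-group physiological parameters.

    Attributes
    ----------
    p_max : maximum specific growth rate at T_ref (d^-1)
    l_d0 : specific death rate at T_ref (d^-1)
    l_exu0 : specific exudation rate at T_ref (d^-1)
    q_P : phosphorus quota (mg P per mg C)
    K_P : half-saturation for dissolved P (mg P m^-3)
    K_I : half-saturation for irradiance (umol m^-2 s^-1)
    C_max : carrying areal density, benthic groups only (mg C m^-2)
    sigma_epi : specific colonizable surface of macrophytes (m^2 per mg C)
    w_live, w_dead : sinking velocities, phyto groups only (m d^-1)
    Q10_growth, Q10_loss : temperature coefficients (>= 1)
    T_ref : reference temperature (degC)
    """

    model_config = ConfigDict(extra="forbid")

    p_max: float
    l_d0: float
    l_exu0: float
    q_P: float = 0.01
    K_P: float = 5.0
    K_I: float = 40.0
    C_max: float | None = None
    sigma_epi: float | None = None
    w_live: float = 0.0
    w_dead: float = 0.0
    Q10_growth: float = 2.0
    Q10_loss: float = 2.0
    T_ref: float = 22.0

    @model_validator(mode="after")
    def _check(self) -> "GroupParameters":
        for name in ("p_max", "l_d0", "l_exu0", "q_P", "w_live", "w_dead"):
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name} must be non-negative")
        for name in ("K_P", "K_I"):
            if not getattr(self, name) > 0:
                raise ValueError(f"parameter {name} must be strictly positive")
        for name in ("Q10_growth", "Q10_loss"):
            if getattr(self, name) < 1:
                raise ValueError(f"parameter {name} must be >= 1")
        if self.C_max is not None and not self.C_max > 0:
            raise ValueError("parameter C_max must be strictly positive")
        if self.sigma_epi is not None and self.sigma_epi < 0:
            raise ValueError("parameter sigma_epi must be non-negative")
        return self


class DecompositionParameters(BaseModel):
    """Biodegradation rates of dead biomass and exudates (d^-1 at T_ref)."""

    model_config = ConfigDict(extra="forbid")

    b_dead0: dict[str, float] = {g: 0.05 for g in ALL_GROUPS}
    b_exu0: dict[str, float] = {g: 0.10 for g in ALL_GROUPS}
    Q10_b: float = 2.0
    T_ref: float = 22.0

    @model_validator(mode="after")
    def _check(self) -> "DecompositionParameters":
        for field in ("b_dead0", "b_exu0"):
            rates = getattr(self, field)
            for g, v in rates.items():
                if g not in ALL_GROUPS:
                    raise ValueError(f"{field}: unknown group {g!r}")
                if v < 0:
                    raise ValueError(f"{field}[{g}] must be non-negative")
            missing = set(ALL_GROUPS) - set(rates)
            if missing:
                raise ValueError(f"{field}: missing groups {sorted(missing)}")
        if self.Q10_b < 1:
            raise ValueError("Q10_b must be >= 1")
        return self


class LightParameters(BaseModel):
    """Light attenuation in the water column and by epiphyton cover.

    k_bg : background extinction of water + dissolved matter (m^-1)
    k_chl : specific extinction of live phytoplankton C (m^2 per mg C)
    k_epi : specific extinction of the epiphyton layer (m^2 per mg C)
    """

    model_config = ConfigDict(extra="forbid")

    k_bg: float = 0.5
    k_chl: float = 4.0e-4
    k_epi: float = 4.0e-4

    @model_validator(mode="after")
    def _check(self) -> "LightParameters":
        if not self.k_bg > 0:
            raise ValueError("k_bg must be strictly positive")
        if self.k_chl < 0 or self.k_epi < 0:
            raise ValueError("k_chl and k_epi must be non-negative")
        return self


class InitialConditions(BaseModel):
    """Initial pool values at treatment application (t = 0).

    phyto_total is split across the phytoplankton groups present in a
    community set. Macrophytes start as the planted shoots' carbon;
    exudate and dead pools start empty; dissolved P starts at the first
    nutrient-pulse amount.
    """

    model_config = ConfigDict(extra="forbid")

    phyto_total: float = 10.0  # mg C m^-3
    periphyton: float = 10.0  # mg C m^-2
    epiphyton: float = 1.0  # mg C (whole microcosm)
    macrophytes: float = 200.0  # mg C (whole microcosm)
    P_d: float = 50.0  # mg P m^-3

    @model_validator(mode="after")
    def _check(self) -> "InitialConditions":
        for name in type(self).model_fields:
            if getattr(self, name) < 0:
                raise ValueError(f"initial condition {name} must be non-negative")
        return self


def default_group_parameters() -> dict[str, GroupParameters]:
    """Default parameter set for the five producer groups.

    Group alpha grows 1.5x faster than group beta; benthic groups carry a
    space cap; only macrophytes expose a colonizable surface; only the
    planktonic groups sink.
    """
    return {
        PHYTO_ALPHA: GroupParameters(
            p_max=1.5, l_d0=0.05, l_exu0=0.03, K_P=5.0, K_I=40.0,
            w_live=0.02, w_dead=0.10,
        ),
        PHYTO_BETA: GroupParameters(
            p_max=1.0, l_d0=0.05, l_exu0=0.03, K_P=5.0, K_I=40.0,
            w_live=0.02, w_dead=0.10,
        ),
        "periphyton": GroupParameters(
            p_max=0.8, l_d0=0.03, l_exu0=0.02, K_P=10.0, K_I=40.0, C_max=2000.0,
        ),
        "epiphyton": GroupParameters(
            p_max=0.8, l_d0=0.03, l_exu0=0.02, K_P=10.0, K_I=40.0, C_max=1000.0,
        ),
        MACROPHYTES: GroupParameters(
            # plant tissue is P-poorer than algae: ~0.2% P of ~40% C dry weight
            p_max=0.15, l_d0=0.01, l_exu0=0.01, q_P=0.005, K_P=5.0, K_I=30.0,
            sigma_epi=1.0e-4,
        ),
    }


def validate_parameter_set(params: dict[str, GroupParameters]) -> None:
    """Cross-group invariants the config layer enforces."""
    missing = set(ALL_GROUPS) - set(params)
    if missing:
        raise ValueError(f"missing group parameters for {sorted(missing)}")
    if PHYTO_ALPHA in params and PHYTO_BETA in params:
        if not params[PHYTO_ALPHA].p_max > params[PHYTO_BETA].p_max:
            raise ValueError("p_max of phyto_alpha must exceed p_max of phyto_beta")
    for g in BENTHIC_GROUPS:
        if params[g].C_max is None:
            raise ValueError(f"benthic group {g} requires C_max")
    if params[MACROPHYTES].sigma_epi is None:
        raise ValueError("macrophytes require sigma_epi")
    for g in PHYTO_GROUPS:
        if params[g].w_live < 0 or params[g].w_dead < 0:
            raise ValueError(f"sinking velocities of {g} must be non-negative")
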