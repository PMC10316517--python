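"""State layout, auxiliary rate laws and the governing ODE right-hand side.

The microcosm is described by carbon pools for each primary-producer group
(live, exudate, dead), a sedimented dead-phytoplankton pool per planktonic
group, and dissolved inorganic phosphorus. Unit regimes differ by habit:

* phytoplankton pools are volume concentrations (mg C m^-3),
* periphyton pools are areal densities on the vessel wall (mg C m^-2),
* epiphyton pools are whole-microcosm masses (mg C) — the colonizable area
  A_epi changes with macrophyte biomass, and tracking mass rather than
  density keeps the phosphorus budget exactly closed under area change,
* macrophyte pools are whole-microcosm masses (mg C),
* exudates of all groups are volume concentrations (mg C m^-3),
* the sediment pool is an areal density on the sediment (mg C m^-2),
* dissolved P is a volume concentration (mg P m^-3).

All process rates are first-order in the donor pool, Q10-scaled with
temperature, and growth is the product of a maximum rate with Monod light
and phosphorus factors, a linear space factor for the benthic groups, and a
toxicant dose-response factor supplied by the stressor layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .geometry import MicrocosmGeometry
from .groups import (
    EPIPHYTON,
    MACROPHYTES,
    PERIPHYTON,
    PHYTO_GROUPS,
    validate_group,
)
from .parameters import (
    DecompositionParameters,
    GroupParameters,
    LightParameters,
)

__all__ = [
    "StateLayout",
    "ModelContext",
    "temperature_factor",
    "nutrient_limitation",
    "light_limitation",
    "space_limitation",
    "epiphyte_area",
    "effective_irradiance",
    "growth_rate",
    "loss_rates",
    "biodegradation_rates",
    "phosphorus_sources",
    "derivatives",
    "total_phosphorus",
]


# ---------------------------------------------------------------------------
# state vector layout
# ---------------------------------------------------------------------------

class StateLayout:
    """Index map from named pools to positions in the flat state vector.

    Order: live C per group, exudate C per group, dead C per group,
    sedimented dead phytoplankton C per phyto group, dissolved P.
    Group order is (present phyto groups..., periphyton, epiphyton,
    macrophytes).
    """

    def __init__(self, phyto_groups: tuple[str, ...]):
        if not phyto_groups or not set(phyto_groups) <= set(PHYTO_GROUPS):
            raise ValueError(
                f"phyto_groups must be a non-empty subset of {PHYTO_GROUPS}"
            )
        self.phyto_groups = tuple(phyto_groups)
        self.groups = self.phyto_groups + (PERIPHYTON, EPIPHYTON, MACROPHYTES)
        n = len(self.groups)
        self.live = {g: i for i, g in enumerate(self.groups)}
        self.exu = {g: n + i for i, g in enumerate(self.groups)}
        self.dead = {g: 2 * n + i for i, g in enumerate(self.groups)}
        self.sed = {p: 3 * n + j for j, p in enumerate(self.phyto_groups)}
        self.i_P = 3 * n + len(self.phyto_groups)
        self.size = self.i_P + 1

    def labels(self) -> list[tuple[str, str]]:
        """(pool, group) pairs in state-vector order; P_d has group ''."""
        out = [("live", g) for g in self.groups]
        out += [("exu", g) for g in self.groups]
        out += [("dead", g) for g in self.groups]
        out += [("dead_sed", p) for p in self.phyto_groups]
        out.append(("P_d", ""))
        return out


@dataclass
class ModelContext:
    """Everything the right-hand side needs besides the state itself."""

    geometry: MicrocosmGeometry
    params: dict[str, GroupParameters]
    decomposition: DecompositionParameters
    light: LightParameters
    layout: StateLayout
    T: float  # water temperature (degC)
    #: (group, t) -> growth multiplier in (0, 1]; identity when no toxicant.
    tox_factor: Callable[[str, float], float] = field(
        default=lambda group, t: 1.0
    )


# ---------------------------------------------------------------------------
# auxiliary rate laws
# ---------------------------------------------------------------------------

def temperature_factor(T: float, T_ref: float, Q10: float) -> float:
    """Q10 multiplier Q10**((T - T_ref)/10); 1 at the reference temperature."""
    if not (math.isfinite(T) and math.isfinite(T_ref)):
        raise ValueError("temperature must be finite")
    if not (math.isfinite(Q10) and Q10 >= 1):
        raise ValueError("Q10 must be finite and >= 1")
    return Q10 ** ((T - T_ref) / 10.0)


def nutrient_limitation(P_d: float, K_P: float) -> float:
    """Monod phosphorus factor P_d / (P_d + K_P) in [0, 1)."""
    if P_d < 0:
        raise ValueError("dissolved P must be non-negative")
    if not K_P > 0:
        raise ValueError("K_P must be strictly positive")
    return P_d / (P_d + K_P)


def light_limitation(I_eff: float, K_I: float) -> float:
    """Monod light factor I_eff / (I_eff + K_I) in [0, 1)."""
    if I_eff < 0:
        raise ValueError("irradiance must be non-negative")
    if not K_I > 0:
        raise ValueError("K_I must be strictly positive")
    return I_eff / (I_eff + K_I)


def space_limitation(C: float, C_max: float) -> float:
    """Linear space factor max(0, 1 - C/C_max); zero at or above capacity."""
    if C < 0:
        raise ValueError("areal density must be non-negative")
    if not C_max > 0:
        raise ValueError("C_max must be strictly positive")
    return max(0.0, 1.0 - C / C_max)


def epiphyte_area(C_live_macro: float, sigma_epi: float) -> float:
    """Colonizable macrophyte surface (m^2), proportional to plant carbon."""
    if C_live_macro < 0 or sigma_epi < 0:
        raise ValueError("macrophyte biomass and sigma_epi must be non-negative")
    return sigma_epi * C_live_macro


def effective_irradiance(
    group: str,
    total_phyto_C: float,
    epi_density: float,
    geometry: MicrocosmGeometry,
    light: LightParameters,
) -> float:
    """Photoperiod-averaged irradiance reaching a group (umol m^-2 s^-1).

    The water column attenuates light following Lambert-Beer with extinction
    k = k_bg + k_chl * total live phytoplankton C. Planktonic groups and the
    wall biofilm receive the depth average of the column profile; macrophytes
    receive mid-depth light further reduced by the epiphyton layer covering
    their surfaces; epiphyton receives mid-depth light on the plant surface.

    Parameters
    ----------
    total_phyto_C : summed live phytoplankton carbon (mg C m^-3)
    epi_density : epiphyton areal density on macrophyte surfaces (mg C m^-2)
    """
    validate_group(group)
    if total_phyto_C < 0 or epi_density < 0:
        raise ValueError("biomass inputs must be non-negative")
    if not light.k_bg > 0:
        raise ValueError("background extinction k_bg must be strictly positive")
    I0 = geometry.mean_irradiance
    k = light.k_bg + light.k_chl * total_phyto_C
    kh = k * geometry.H
    if group in PHYTO_GROUPS or group == PERIPHYTON:
        # depth average of I0 * exp(-k z) over [0, H]
        return I0 * (1.0 - math.exp(-kh)) / kh
    mid = I0 * math.exp(-kh / 2.0)
    if group == EPIPHYTON:
        return mid
    # macrophytes: below their epiphyton cover
    return mid * math.exp(-light.k_epi * epi_density)


def growth_rate(
    group: str,
    state: np.ndarray,
    ctx: ModelContext,
    tox_factor: float = 1.0,
) -> float:
    """Specific growth rate p (d^-1) of one group at the given state.

    p = p_max * f_T * f_light * f_P * f_space (benthic only) * tox_factor.
    Macrophytes take phosphorus from the water column, so their f_P uses
    dissolved P like every other group.
    """
    validate_group(group)
    if not (0.0 < tox_factor <= 1.0):
        raise ValueError("tox_factor must lie in (0, 1]")
    params = ctx.params[group]
    lay = ctx.layout
    f_T = temperature_factor(ctx.T, params.T_ref, params.Q10_growth)
    total_phyto = float(sum(state[lay.live[p]] for p in lay.phyto_groups))
    A_epi = epiphyte_area(
        float(state[lay.live[MACROPHYTES]]), ctx.params[MACROPHYTES].sigma_epi
    )
    epi_density = float(state[lay.live[EPIPHYTON]]) / A_epi if A_epi > 0 else 0.0
    I_eff = effective_irradiance(group, total_phyto, epi_density, ctx.geometry, ctx.light)
    f_I = light_limitation(I_eff, params.K_I)
    f_P = nutrient_limitation(float(state[lay.i_P]), params.K_P)
    if group == PERIPHYTON:
        f_S = space_limitation(float(state[lay.live[PERIPHYTON]]), params.C_max)
    elif group == EPIPHYTON:
        # no macrophyte surface -> no habitat -> no growth
        f_S = space_limitation(epi_density, params.C_max) if A_epi > 0 else 0.0
    else:
        f_S = 1.0
    return params.p_max * f_T * f_I * f_P * f_S * tox_factor


def loss_rates(params: GroupParameters, T: float) -> tuple[float, float, float]:
    """(l_d, l_exu, l) in d^-1: death, exudation and their Q10-scaled sum."""
    f_T = temperature_factor(T, params.T_ref, params.Q10_loss)
    l_d = params.l_d0 * f_T
    l_exu = params.l_exu0 * f_T
    return l_d, l_exu, l_d + l_exu


def biodegradation_rates(
    decomp: DecompositionParameters, T: float
) -> tuple[dict[str, float], dict[str, float]]:
    """Q10-scaled (b_dead, b_exu) per group, applied to all detrital pools."""
    f_T = temperature_factor(T, decomp.T_ref, decomp.Q10_b)
    b_dead = {g: v * f_T for g, v in decomp.b_dead0.items()}
    b_exu = {g: v * f_T for g, v in decomp.b_exu0.items()}
    return b_dead, b_exu


def phosphorus_sources(
    state: np.ndarray,
    p_rates: dict[str, float],
    ctx: ModelContext,
    b_dead: dict[str, float],
    b_exu: dict[str, float],
) -> dict[str, float]:
    """Net P source of each group family (mg P m^-3 d^-1), volume basis.

    Biodegradation of dead and exudate pools releases P at the producer's
    quota; growth uptake removes it. Areal and whole-microcosm pools are
    converted to the water-volume basis before quota weighting.
    """
    geo, lay = ctx.geometry, ctx.layout
    out: dict[str, float] = {}
    s_phyto = 0.0
    for p in lay.phyto_groups:
        q = ctx.params[p].q_P
        s_phyto += q * (
            b_dead[p] * state[lay.dead[p]]
            + b_exu[p] * state[lay.exu[p]]
            + b_dead[p] * state[lay.sed[p]] * geo.A_sed / geo.V
            - p_rates[p] * state[lay.live[p]]
        )
    out["phyto"] = float(s_phyto)
    q = ctx.params[PERIPHYTON].q_P
    out["peri"] = float(
        q
        * (
            b_dead[PERIPHYTON] * state[lay.dead[PERIPHYTON]] * geo.A_peri / geo.V
            + b_exu[PERIPHYTON] * state[lay.exu[PERIPHYTON]]
            - p_rates[PERIPHYTON] * state[lay.live[PERIPHYTON]] * geo.A_peri / geo.V
        )
    )
    q = ctx.params[EPIPHYTON].q_P
    out["epi"] = float(
        q
        * (
            b_dead[EPIPHYTON] * state[lay.dead[EPIPHYTON]] / geo.V
            + b_exu[EPIPHYTON] * state[lay.exu[EPIPHYTON]]
            - p_rates[EPIPHYTON] * state[lay.live[EPIPHYTON]] / geo.V
        )
    )
    q = ctx.params[MACROPHYTES].q_P
    out["macro"] = float(
        q
        * (
            b_dead[MACROPHYTES] * state[lay.dead[MACROPHYTES]] / geo.V
            + b_exu[MACROPHYTES] * state[lay.exu[MACROPHYTES]]
            - p_rates[MACROPHYTES] * state[lay.live[MACROPHYTES]] / geo.V
        )
    )
    return out


# ---------------------------------------------------------------------------
# governing equations
# ---------------------------------------------------------------------------

def _rhs(t: float, state: np.ndarray, ctx: ModelContext) -> np.ndarray:
    """Right-hand side used by the integrator; tiny negative excursions the
    solver produces are treated as zero when evaluating rate laws."""
    y = np.maximum(state, 0.0)
    geo, lay = ctx.geometry, ctx.layout
    dy = np.zeros_like(y)

    p_rates = {
        g: growth_rate(g, y, ctx, ctx.tox_factor(g, t)) for g in lay.groups
    }
    losses = {g: loss_rates(ctx.params[g], ctx.T) for g in lay.groups}
    b_dead, b_exu = biodegradation_rates(ctx.decomposition, ctx.T)

    for p in lay.phyto_groups:
        prm = ctx.params[p]
        l_d, l_exu, l = losses[p]
        C = y[lay.live[p]]
        Cd = y[lay.dead[p]]
        dy[lay.live[p]] = (p_rates[p] - l - prm.w_live / geo.H) * C
        dy[lay.exu[p]] = l_exu * C - b_exu[p] * y[lay.exu[p]]
        dy[lay.dead[p]] = l_d * C - (prm.w_dead / geo.H + b_dead[p]) * Cd
        dy[lay.sed[p]] = (
            prm.w_live * C + prm.w_dead * Cd - b_dead[p] * y[lay.sed[p]]
        )

    # periphyton (areal), epiphyton and macrophytes (whole-microcosm mass)
    for g, conv in ((PERIPHYTON, geo.A_peri / geo.V), (EPIPHYTON, 1.0 / geo.V),
                    (MACROPHYTES, 1.0 / geo.V)):
        l_d, l_exu, l = losses[g]
        C = y[lay.live[g]]
        dy[lay.live[g]] = (p_rates[g] - l) * C
        dy[lay.exu[g]] = l_exu * C * conv - b_exu[g] * y[lay.exu[g]]
        dy[lay.dead[g]] = l_d * C - b_dead[g] * y[lay.dead[g]]

    S = phosphorus_sources(y, p_rates, ctx, b_dead, b_exu)
    dy[lay.i_P] = S["phyto"] + S["peri"] + S["epi"] + S["macro"]
    return dy


def derivatives(state: np.ndarray, t: float, ctx: ModelContext) -> np.ndarray:
    """Validated time derivative of the full state vector (pool units / d)."""
    state = np.asarray(state, dtype=float)
    if state.shape != (ctx.layout.size,):
        raise ValueError(
            f"state must have shape ({ctx.layout.size},), got {state.shape}"
        )
    if np.any(~np.isfinite(state)):
        raise ValueError("state contains non-finite values")
    if np.any(state < -1e-9):
        idx = int(np.argmin(state))
        pool, group = ctx.layout.labels()[idx]
        raise ValueError(
            f"state pool {pool}/{group or 'P'} is negative beyond tolerance "
            f"({state[idx]:.3e}) at t={t}"
        )
    return _rhs(t, state, ctx)


def total_phosphorus(state: np.ndarray, ctx: ModelContext) -> float:
    """Whole-system P on the water-volume basis (mg P m^-3).

    Dissolved P plus the quota-weighted carbon of every pool, areal and
    whole-microcosm pools converted per unit water volume. Conserved by the
    governing equations between nutrient pulses.
    """
    geo, lay = ctx.geometry, ctx.layout
    total = float(state[lay.i_P])
    for p in lay.phyto_groups:
        q = ctx.params[p].q_P
        total += q * float(
            state[lay.live[p]] + state[lay.exu[p]] + state[lay.dead[p]]
            + state[lay.sed[p]] * geo.A_sed / geo.V
        )
    for g, conv in ((PERIPHYTON, geo.A_peri / geo.V), (EPIPHYTON, 1.0 / geo.V),
                    (MACROPHYTES, 1.0 / geo.V)):
        q = ctx.params[g].q_P
        total += q * float(
            (state[lay.live[g]] + state[lay.dead[g]]) * conv + state[lay.exu[g]]
        )
    return total
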