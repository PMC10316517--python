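"""Herbicide exposure dynamics and dose-response modulation of growth.

Of the run-off constituents only the herbicide (a PSII inhibitor) acts on
the modelled producers; the insecticide, fungicide and copper are carried in
the treatment definition for reporting but are inert here. Exposure follows
an immediate application loss and first-order decay. The growth multiplier
is a log-logistic inhibition curve whose EC50 can depend on temperature and,
for the microscopic groups under tolerance scenarios, rise over time
(pollution-induced community tolerance), with a time constant tied to each
group's generation time through 1/p_max.
"""

from __future__ import annotations

import math

from pydantic import BaseModel, ConfigDict, model_validator

from .groups import MACROPHYTES, MICROSCOPIC_GROUPS, validate_group

#: Temperatures of the two climate chambers (degC); a treatment is "warm"
#: when it is closer to WARM_T than to COOL_T.
COOL_T = 22.0
WARM_T = 26.0


class ToxicantCourse(BaseModel):
    """Dissolved herbicide concentration over one exposure.

    c(t) = c_nominal * (1 - loss_frac_application) * exp(-k_decay * t).

    Defaults: 10% immediate loss at application, and a decay constant such
    that 70% of the post-application concentration remains at day 18
    (within the 55-90% range seen in end-of-exposure water samples).
    Decay is temperature-independent.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    c_nominal: float  # ug L^-1
    loss_frac_application: float = 0.10
    k_decay: float = -math.log(0.70) / 18.0  # d^-1, ~0.01982

    @model_validator(mode="after")
    def _check(self) -> "ToxicantCourse":
        if self.c_nominal < 0:
            raise ValueError("c_nominal must be non-negative")
        if not (0 <= self.loss_frac_application < 1):
            raise ValueError("loss_frac_application must lie in [0, 1)")
        if self.k_decay < 0:
            raise ValueError("k_decay must be non-negative")
        return self


class DoseResponse(BaseModel):
    """Log-logistic dose-response of one group under one scenario.

    ec50_initial/ec50_final bound the tolerance trajectory (equal when no
    tolerance develops); hill is the curve steepness; tau_tol the tolerance
    time constant (d); theta_T the EC50 multiplier applied in the warm
    treatment when the scenario is temperature-dependent.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    ec50_initial: float  # ug L^-1
    ec50_final: float  # ug L^-1
    hill: float = 1.0
    tau_tol: float = 1.0  # d
    theta_T: float = 1.0

    @model_validator(mode="after")
    def _check(self) -> "DoseResponse":
        if not self.ec50_initial > 0:
            raise ValueError("ec50_initial must be strictly positive")
        if self.ec50_final < self.ec50_initial:
            raise ValueError("ec50_final must be >= ec50_initial")
        if not self.hill > 0:
            raise ValueError("hill slope must be strictly positive")
        if not self.tau_tol > 0:
            raise ValueError("tau_tol must be strictly positive")
        if self.theta_T < 1:
            raise ValueError("theta_T must be >= 1")
        return self


def toxicant_concentration(course: ToxicantCourse, t: float) -> float:
    """Dissolved herbicide concentration (ug L^-1) at time t (d)."""
    if t < 0:
        raise ValueError("time must be non-negative")
    return (
        course.c_nominal
        * (1.0 - course.loss_frac_application)
        * math.exp(-course.k_decay * t)
    )


def log_logistic_inhibition(c: float, ec50: float, hill: float) -> float:
    """Growth multiplier 1 / (1 + (c/ec50)**hill) in (0, 1]."""
    if c < 0:
        raise ValueError("concentration must be non-negative")
    if not ec50 > 0:
        raise ValueError("ec50 must be strictly positive")
    if not hill > 0:
        raise ValueError("hill slope must be strictly positive")
    return 1.0 / (1.0 + (c / ec50) ** hill)


def ec50_from_ec20(ec20: float, hill: float) -> float:
    """EC50 implied by an EC20 on the same log-logistic curve.

    Solving 1/(1 + (EC20/EC50)**h) = 0.8 gives EC50 = EC20 * 4**(1/h).
    """
    if not ec20 > 0:
        raise ValueError("ec20 must be strictly positive")
    if not hill > 0:
        raise ValueError("hill slope must be strictly positive")
    return ec20 * 4.0 ** (1.0 / hill)


def effective_ec50(group: str, t: float, T: float, scenario, dr: DoseResponse) -> float:
    """Time- and temperature-resolved EC50 (ug L^-1) for one group.

    EC50(t, T) = [e0 + (ef - e0) * (1 - exp(-t / tau_tol))] * theta,
    where theta = dr.theta_T in the warm treatment of a temperature-dependent
    scenario and 1 otherwise. Tolerance (ef > e0) only ever applies to the
    microscopic groups of D scenarios; the macrophyte EC50 is constant in
    time in every scenario.

    Parameters
    ----------
    scenario : ScenarioConfig with flags ``temperature_dependent`` and
        ``tolerance_development``.
    """
    validate_group(group)
    if t < 0:
        raise ValueError("time must be non-negative")
    tolerant = (
        scenario.tolerance_development
        and group in MICROSCOPIC_GROUPS
        and dr.ec50_final > dr.ec50_initial
    )
    if group == MACROPHYTES and dr.ec50_final > dr.ec50_initial:
        raise ValueError("macrophytes cannot carry a tolerance trajectory")
    if tolerant:
        ec50 = dr.ec50_initial + (dr.ec50_final - dr.ec50_initial) * (
            1.0 - math.exp(-t / dr.tau_tol)
        )
    else:
        ec50 = dr.ec50_initial
    if scenario.temperature_dependent and T > (COOL_T + WARM_T) / 2:
        ec50 *= dr.theta_T
    return ec50


def build_dose_responses(
    scenario,
    p_max: dict[str, float],
    base_ec50: float = 3.0,
    hill: float = 1.0,
    tolerance_final_factor: float = 16.0,
    kappa_tol: float = 40.0,
    theta_T: float = 2.0,
) -> dict[str, DoseResponse]:
    """Per-group dose-response curves implied by a sensitivity scenario.

    The anchor ``base_ec50`` (default 3 ug/L, from an EC20 of 0.75 ug/L at
    hill = 1, the herbicide's 1x run-off concentration) is scaled by each
    group's scenario multiplier. Under tolerance scenarios the microscopic
    groups' EC50 rises toward ``tolerance_final_factor`` times its initial
    value with tau = kappa_tol / p_max, so faster growers adapt faster.

    Parameters
    ----------
    scenario : ScenarioConfig providing ``sensitivity_ordering`` (group ->
        EC50 multiplier) and the tolerance flag.
    p_max : maximum growth rate per group (d^-1), setting generation times.
    """
    out: dict[str, DoseResponse] = {}
    for group, mult in scenario.sensitivity_ordering.items():
        e0 = base_ec50 * mult
        tolerant = scenario.tolerance_development and group in MICROSCOPIC_GROUPS
        ef = e0 * tolerance_final_factor if tolerant else e0
        tau = kappa_tol / p_max[group] if tolerant else 1.0
        out[group] = DoseResponse(
            ec50_initial=e0, ec50_final=ef, hill=hill, tau_tol=tau, theta_T=theta_T
        )
    return out
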