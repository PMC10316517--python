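"""Synthetic endpoint observations with the experiment's design structure.

No replicate-level observations are published for the underlying
experiment, so assessment and scenario selection are exercised against
synthetic observation sets: per-cell mean endpoint biomasses (6 run-off
levels x 2 temperatures x 3 groups) with lognormal replicate noise.
The shipped default pattern encodes the reported qualitative responses:
cool-treatment macrophytes depressed at every run-off level relative to the
control, warm macrophytes flat, phytoplankton rising with run-off level
(with an irregular dip at 8x), and periphyton flat with large replicate
scatter, largest in the controls. Observation sets can also be derived from
simulated endpoints for recovery experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .groups import ASSESSMENT_GROUPS
from .scenarios import ARO_LEVELS, TEMPERATURES


@dataclass(frozen=True)
class PatternSpec:
    """Mean response curves plus replicate-noise structure.

    means maps (group, temperature) -> 6 per-level mean biomasses
    (arbitrary but consistent units); cv is the lognormal coefficient of
    variation per group; cv_overrides optionally inflates single cells
    (group, temperature, aro_level) -> cv.
    """

    means: dict[tuple[str, float], tuple[float, ...]]
    cv: dict[str, float]
    n_reps: int = 6
    cv_overrides: dict[tuple[str, float, int], float] = field(default_factory=dict)

    def validate(self) -> None:
        if not (2 <= self.n_reps <= 20):
            raise ValueError("n_reps must lie in [2, 20]")
        for key, curve in self.means.items():
            if len(curve) != len(ARO_LEVELS):
                raise ValueError(f"cell {key}: need {len(ARO_LEVELS)} means")
            if any(m < 0 for m in curve):
                raise ValueError(f"cell {key}: means must be non-negative")
        for g, cv in self.cv.items():
            if not cv > 0:
                raise ValueError(f"cv for {g} must be strictly positive")
        for key, cv in self.cv_overrides.items():
            if not cv > 0:
                raise ValueError(f"cv override {key} must be strictly positive")


def default_pattern_spec(n_reps: int = 6) -> PatternSpec:
    """Shipped pattern emulating the experiment's qualitative endpoint
    responses, on each group's sampling basis (mg dry weight): macrophytes
    per microcosm, periphyton per sampled strip set, phytoplankton per m^3
    of water (so that upscaling converts by the water volume)."""
    means = {
        # cool macrophytes: control high, all run-off levels depressed and flat
        ("macrophytes", 22.0): (1000.0, 600.0, 590.0, 580.0, 570.0, 560.0),
        # warm macrophytes: no response to run-off
        ("macrophytes", 26.0): (800.0, 795.0, 805.0, 790.0, 800.0, 792.0),
        # phytoplankton: rising with run-off, irregular dip at 8x
        ("phytoplankton", 22.0): (6000.0, 7500.0, 11000.0, 16000.0, 12500.0,
                                  22000.0),
        ("phytoplankton", 26.0): (7500.0, 9000.0, 12000.0, 19000.0, 16000.0,
                                  27000.0),
        # periphyton: flat means, heavy scatter
        ("periphyton", 22.0): (300.0, 310.0, 295.0, 305.0, 290.0, 285.0),
        ("periphyton", 26.0): (320.0, 315.0, 330.0, 310.0, 300.0, 295.0),
    }
    cv = {"macrophytes": 0.25, "phytoplankton": 0.35, "periphyton": 0.5}
    overrides = {
        ("periphyton", 22.0, 0): 1.0,  # inflated control variance
        ("periphyton", 26.0, 0): 1.0,
    }
    return PatternSpec(means=means, cv=cv, n_reps=n_reps, cv_overrides=overrides)


def _lognormal(rng: np.random.Generator, mean: float, cv: float, n: int) -> np.ndarray:
    """n lognormal draws with the requested arithmetic mean and CV."""
    if mean == 0.0:
        return np.zeros(n)
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n)


def generate_observations(spec: PatternSpec, seed: int) -> pd.DataFrame:
    """Replicate endpoint table drawn from a pattern specification.

    Returns columns group, temperature, aro_level, replicate, biomass.
    The same seed always yields the same table.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    rows = []
    for (group, temp), curve in sorted(spec.means.items()):
        for level, mean in zip(ARO_LEVELS, curve):
            cv = spec.cv_overrides.get((group, temp, level), spec.cv[group])
            draws = _lognormal(rng, mean, cv, spec.n_reps)
            for rep, value in enumerate(draws, start=1):
                rows.append((group, temp, level, rep, float(value)))
    return pd.DataFrame(
        rows, columns=["group", "temperature", "aro_level", "replicate", "biomass"]
    )


def observations_from_simulation(
    endpoints: pd.DataFrame,
    cv: float | dict[str, float],
    n_reps: int,
    seed: int,
) -> pd.DataFrame:
    """Noisy observation set using simulated endpoints as cell means.

    The endpoint table must cover all 12 treatments for each assessment
    group. cv may be a scalar or a per-group mapping; cv = 0 degenerates to
    the simulated endpoints themselves.
    """
    expected = {
        (g, t, lvl)
        for g in ASSESSMENT_GROUPS
        for t in TEMPERATURES
        for lvl in ARO_LEVELS
    }
    have = {
        (r.group, float(r.temperature), int(r.aro_level))
        for r in endpoints.itertuples()
        if r.group in ASSESSMENT_GROUPS
    }
    missing = expected - have
    if missing:
        raise ValueError(f"endpoint table incomplete: missing {sorted(missing)[:3]}...")
    if not (2 <= n_reps <= 20):
        raise ValueError("n_reps must lie in [2, 20]")
    cv_map = cv if isinstance(cv, dict) else {g: cv for g in ASSESSMENT_GROUPS}
    rng = np.random.default_rng(seed)
    rows = []
    cells = endpoints[endpoints["group"].isin(ASSESSMENT_GROUPS)].sort_values(
        ["group", "temperature", "aro_level"]
    )
    for r in cells.itertuples():
        cv_g = cv_map[r.group]
        if cv_g == 0:
            draws = np.full(n_reps, float(r.biomass))
        else:
            draws = _lognormal(rng, float(r.biomass), cv_g, n_reps)
        for rep, value in enumerate(draws, start=1):
            rows.append(
                (r.group, float(r.temperature), int(r.aro_level), rep, float(value))
            )
    return pd.DataFrame(
        rows, columns=["group", "temperature", "aro_level", "replicate", "biomass"]
    )
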