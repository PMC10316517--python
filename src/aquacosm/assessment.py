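"""Pattern-oriented model assessment and scenario selection.

Simulated endpoint-biomass response curves (biomass vs run-off level, per
group and temperature) are compared with observed replicate data through
Pearson correlations over the six levels, with two-sided p-values from the
t distribution at n - 2 degrees of freedom and starred significance tiers
(90/95/99%). Effect sizes use Hedges' g with the small-sample correction.
The selection procedure eliminates scenarios in three stages: macrophyte
correlations must be positive and significant at both temperatures, the
phytoplankton correlation must be positive at at least one temperature, and
remaining candidates are ranked on periphyton correlation significance and
magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import MicrocosmGeometry
from .groups import ASSESSMENT_GROUPS

TIER_NS = "ns"
TIER_90 = "90%"
TIER_95 = "95%"
TIER_99 = "99%"
_SIGNIFICANT_TIERS = (TIER_90, TIER_95, TIER_99)


def tier_from_p(p: float) -> str:
    """Starred confidence tier for a two-sided p-value."""
    if not (0 <= p <= 1):
        raise ValueError("p-value must lie in [0, 1]")
    if p < 0.01:
        return TIER_99
    if p < 0.05:
        return TIER_95
    if p < 0.1:
        return TIER_90
    return TIER_NS


def p_from_r(r: float, n: int) -> float:
    """Two-sided p for a Pearson r on n pairs (t statistic, n-2 df)."""
    if not (-1 <= r <= 1):
        raise ValueError("correlation must lie in [-1, 1]")
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


@dataclass(frozen=True)
class CorrelationEntry:
    """Simulated-vs-observed response-curve correlation for one cell."""

    group: str
    temperature: float
    r: float
    p: float
    tier: str

    @property
    def significant(self) -> bool:
        return self.tier in _SIGNIFICANT_TIERS

    @classmethod
    def from_r(cls, group: str, temperature: float, r: float, n: int = 6):
        """Build an entry from a correlation coefficient alone, re-deriving
        p and tier for n response-curve points."""
        p = p_from_r(r, n)
        return cls(group=group, temperature=temperature, r=float(r), p=p,
                   tier=tier_from_p(p))


def response_correlation(
    sim: pd.DataFrame, obs: pd.DataFrame
) -> list[CorrelationEntry]:
    """Correlate simulated and observed endpoint curves per group x temperature.

    Parameters
    ----------
    sim : endpoint table with columns group, temperature, aro_level, biomass.
    obs : observation table with columns group, temperature, aro_level,
        replicate, biomass; replicates are collapsed to cell means.

    The curves must share at least 3 run-off levels; zero variance on either
    side leaves the correlation undefined and raises.
    """
    obs_means = (
        obs.groupby(["group", "temperature", "aro_level"], as_index=False)["biomass"]
        .mean()
    )
    entries: list[CorrelationEntry] = []
    for (group, temp), sim_cell in sim.groupby(["group", "temperature"]):
        obs_cell = obs_means[
            (obs_means["group"] == group) & (obs_means["temperature"] == temp)
        ]
        merged = sim_cell.merge(
            obs_cell, on="aro_level", suffixes=("_sim", "_obs")
        ).sort_values("aro_level")
        if len(merged) < 3:
            raise ValueError(
                f"fewer than 3 shared run-off levels for {group} at {temp} degC"
            )
        x = merged["biomass_sim"].to_numpy(float)
        y = merged["biomass_obs"].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError(
                f"zero variance in the {group} curve at {temp} degC; "
                "correlation undefined"
            )
        res = stats.pearsonr(x, y)
        entries.append(
            CorrelationEntry(
                group=group,
                temperature=float(temp),
                r=float(res.statistic),
                p=float(res.pvalue),
                tier=tier_from_p(float(res.pvalue)),
            )
        )
    return entries


def correlation_frame(entries: list[CorrelationEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": e.group,
                "temperature": e.temperature,
                "r": e.r,
                "p": e.p,
                "tier": e.tier,
            }
            for e in entries
        ]
    )


def hedges_g(treatment: np.ndarray, control: np.ndarray) -> tuple[float, float]:
    """Bias-corrected standardized mean difference (Hedges' g) and its SE.

    g = J * (mean_t - mean_c) / s_pooled with the small-sample correction
    J = 1 - 3 / (4 (n_t + n_c) - 9); positive when the treatment mean
    exceeds the control mean. The variance follows Hedges & Olkin's
    large-sample approximation.
    """
    t = np.asarray(treatment, float)
    c = np.asarray(control, float)
    n1, n2 = len(t), len(c)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 replicates per group")
    s_pooled = np.sqrt(
        ((n1 - 1) * np.var(t, ddof=1) + (n2 - 1) * np.var(c, ddof=1))
        / (n1 + n2 - 2)
    )
    if s_pooled == 0:
        raise ValueError("pooled standard deviation is zero; effect undefined")
    d = (t.mean() - c.mean()) / s_pooled
    J = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    g = J * d
    var_g = J**2 * ((n1 + n2) / (n1 * n2) + d**2 / (2.0 * (n1 + n2 - 2)))
    return float(g), float(np.sqrt(var_g))


def upscale_to_microcosm(
    rows: pd.DataFrame,
    geometry: MicrocosmGeometry | None = None,
    reference: tuple[float, int] | None = (22.0, 0),
) -> pd.DataFrame:
    """Whole-microcosm totals, group shares and relative total per treatment.

    Periphyton sampled on strips is scaled by wall area / strip area;
    phytoplankton concentrations by the water volume; macrophyte totals pass
    through. Rows whose ``basis`` column already says ``whole-microcosm``
    are not rescaled. Shares sum to 1 within each (temperature, aro_level)
    cell; ``relative_total`` divides each cell total by the reference cell's
    (default: the cool control).
    """
    geometry = geometry or MicrocosmGeometry()
    df = rows.copy()
    if "replicate" in df.columns:
        df = (
            df.groupby(["group", "temperature", "aro_level"], as_index=False)[
                "biomass"
            ].mean()
        )
    missing = set(ASSESSMENT_GROUPS) - set(df["group"].unique())
    if missing and len(df["group"].unique()) > 1:
        raise ValueError(f"missing groups for upscaling: {sorted(missing)}")

    already_total = (
        rows["basis"].astype(str).str.contains("whole-microcosm").all()
        if "basis" in rows.columns
        else False
    )

    def scale(row) -> float:
        if already_total:
            return row["biomass"]
        if row["group"] == "periphyton":
            return row["biomass"] * geometry.A_peri / geometry.A_strip
        if row["group"] == "phytoplankton":
            return row["biomass"] * geometry.V
        return row["biomass"]

    df["total"] = df.apply(scale, axis=1)
    cell_tot = df.groupby(["temperature", "aro_level"])["total"].transform("sum")
    df["share"] = df["total"] / cell_tot
    out = df[["group", "temperature", "aro_level", "total", "share"]].copy()
    if reference is not None:
        ref_temp, ref_level = reference
        ref_mask = (df["temperature"] == ref_temp) & (df["aro_level"] == ref_level)
        if not ref_mask.any():
            raise ValueError(f"reference cell {reference} absent from the table")
        ref_total = df.loc[ref_mask, "total"].sum()
        totals = df.groupby(["temperature", "aro_level"])["total"].transform("sum")
        out["relative_total"] = totals / ref_total
    return out


@dataclass
class SelectionResult:
    """Outcome of the staged scenario elimination, with an audit trail."""

    stage1_survivors: list[str]
    stage2_survivors: list[str]
    selected: str | None
    audit: list[str] = field(default_factory=list)


def select_scenario(
    correlations: dict[str, list[CorrelationEntry]]
) -> SelectionResult:
    """Pick the most plausible scenario from per-scenario correlation tables.

    Stage 1 keeps scenarios whose macrophyte correlation is positive and
    significant (tier >= 90%) at BOTH temperatures. Stage 2 keeps those with
    a positive phytoplankton correlation at >= 1 temperature. Stage 3 ranks
    survivors lexicographically by (number of significant periphyton
    correlations, summed periphyton r, summed macrophyte r) and selects the
    top. Input order never affects the outcome.

    Parameters
    ----------
    correlations : mapping scenario id -> entries covering the 3 assessment
        groups x 2 temperatures.
    """
    audit: list[str] = []
    by_cell: dict[str, dict[tuple[str, float], CorrelationEntry]] = {}
    for sid in sorted(correlations):
        cells = {(e.group, e.temperature): e for e in correlations[sid]}
        for group in ASSESSMENT_GROUPS:
            for temp in (22.0, 26.0):
                if (group, temp) not in cells:
                    raise ValueError(
                        f"scenario {sid}: missing correlation for {group} "
                        f"at {temp} degC"
                    )
        by_cell[sid] = cells

    stage1 = []
    for sid in sorted(by_cell):
        macro = [by_cell[sid][("macrophytes", t)] for t in (22.0, 26.0)]
        if all(e.r > 0 and e.significant for e in macro):
            stage1.append(sid)
        else:
            audit.append(
                f"stage 1: discard {sid} (macrophyte correlation not positive "
                "and significant at both temperatures)"
            )
    audit.append(f"stage 1 survivors: {stage1}")

    stage2 = []
    for sid in stage1:
        phyto = [by_cell[sid][("phytoplankton", t)] for t in (22.0, 26.0)]
        if any(e.r > 0 for e in phyto):
            stage2.append(sid)
        else:
            audit.append(
                f"stage 2: discard {sid} (no positive phytoplankton "
                "correlation at either temperature)"
            )
    audit.append(f"stage 2 survivors: {stage2}")

    selected = None
    if stage2:
        def rank_key(sid: str):
            peri = [by_cell[sid][("periphyton", t)] for t in (22.0, 26.0)]
            macro = [by_cell[sid][("macrophytes", t)] for t in (22.0, 26.0)]
            return (
                sum(e.significant for e in peri),
                sum(e.r for e in peri),
                sum(e.r for e in macro),
            )

        ranked = sorted(stage2, key=rank_key, reverse=True)
        for sid in ranked:
            audit.append(
                f"stage 3 ranking: {sid} -> (significant periphyton cells, "
                f"sum periphyton r, sum macrophyte r) = {rank_key(sid)}"
            )
        selected = ranked[0]
    audit.append(f"selected: {selected}")
    return SelectionResult(
        stage1_survivors=stage1,
        stage2_survivors=stage2,
        selected=selected,
        audit=audit,
    )
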