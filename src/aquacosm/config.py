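"""Structured run configuration: schema, YAML loading and round-tripping.

A run configuration bundles everything a simulation campaign needs:
geometry, per-group physiology, decomposition, light, initial conditions,
dose-response defaults, toxicant-course defaults, the dosing schedule,
solver options, the endpoint day and the base seed. Unknown keys are
rejected; every validation error names the offending key. An empty (or
absent) file yields the shipped defaults.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from .geometry import MicrocosmGeometry
from .parameters import (
    DecompositionParameters,
    GroupParameters,
    InitialConditions,
    LightParameters,
    default_group_parameters,
    validate_parameter_set,
)
from .scenarios import EXPOSURE_DAYS, dosing_schedule
from .simulate import ModelSetup, SolverOptions


class DoseResponseDefaults(BaseModel):
    """Anchors of the scenario dose-response construction.

    base_ec50: EC50 (ug L^-1) of the sensitive anchor group at multiplier 1
    (default 3, from an EC20 of 0.75 ug/L at hill = 1); hill: slope shared
    by all curves; tolerance_final_factor: EC50_final / EC50_initial for
    microscopic groups under D scenarios; kappa_tol: dimensionless tolerance
    pace (tau = kappa_tol / p_max); theta_T: warm-treatment EC50 multiplier
    under '2' scenarios.
    """

    model_config = ConfigDict(extra="forbid")

    base_ec50: float = 3.0
    hill: float = 1.0
    tolerance_final_factor: float = 16.0
    kappa_tol: float = 40.0
    theta_T: float = 2.0

    @model_validator(mode="after")
    def _check(self) -> "DoseResponseDefaults":
        for name in ("base_ec50", "hill", "kappa_tol"):
            if not getattr(self, name) > 0:
                raise ValueError(f"dose_response.{name} must be strictly positive")
        if self.tolerance_final_factor < 1:
            raise ValueError("dose_response.tolerance_final_factor must be >= 1")
        if self.theta_T < 1:
            raise ValueError("dose_response.theta_T must be >= 1")
        return self


class ToxicantDefaults(BaseModel):
    """Application loss and first-order decay of the herbicide."""

    model_config = ConfigDict(extra="forbid")

    loss_frac_application: float = 0.10
    k_decay: float | None = None  # None -> ToxicantCourse default

    @model_validator(mode="after")
    def _check(self) -> "ToxicantDefaults":
        if not (0 <= self.loss_frac_application < 1):
            raise ValueError("toxicant.loss_frac_application must lie in [0, 1)")
        if self.k_decay is not None and self.k_decay < 0:
            raise ValueError("toxicant.k_decay must be non-negative")
        return self


class SolverConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    rtol: float = 1e-6
    atol: float = 1e-9
    method: str = "LSODA"
    samples_per_day: int = 4

    @model_validator(mode="after")
    def _check(self) -> "SolverConfig":
        if not (0 < self.rtol < 1) or not (0 < self.atol < 1):
            raise ValueError("solver tolerances must lie in (0, 1)")
        if self.samples_per_day < 1:
            raise ValueError("solver.samples_per_day must be >= 1")
        return self


class DosingConfig(BaseModel):
    """Twice-weekly nutrient-pulse schedule parameters."""

    model_config = ConfigDict(extra="forbid")

    P_per_event: float = 50.0  # mg P m^-3
    NO3_N_per_event: float = 0.0  # mg m^-3, reporting only

    @model_validator(mode="after")
    def _check(self) -> "DosingConfig":
        if self.P_per_event < 0 or self.NO3_N_per_event < 0:
            raise ValueError("dosing additions must be non-negative")
        return self


class RunConfig(BaseModel):
    """Complete validated configuration of a simulation campaign."""

    model_config = ConfigDict(extra="forbid")

    geometry: MicrocosmGeometry = MicrocosmGeometry()
    groups: dict[str, GroupParameters] = None  # filled by validator
    decomposition: DecompositionParameters = DecompositionParameters()
    light: LightParameters = LightParameters()
    initial: InitialConditions = InitialConditions()
    dose_response: DoseResponseDefaults = DoseResponseDefaults()
    toxicant: ToxicantDefaults = ToxicantDefaults()
    dosing: DosingConfig = DosingConfig()
    solver: SolverConfig = SolverConfig()
    duration_d: float = EXPOSURE_DAYS
    endpoint_day: float = EXPOSURE_DAYS
    seed: int = 0

    @model_validator(mode="before")
    @classmethod
    def _fill_groups(cls, data):
        if isinstance(data, dict) and data.get("groups") is None:
            data = dict(data)
            data["groups"] = {
                g: p.model_dump() for g, p in default_group_parameters().items()
            }
        return data

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        validate_parameter_set(self.groups)
        if not self.duration_d > 0:
            raise ValueError("duration_d must be strictly positive")
        if not (0 <= self.endpoint_day <= self.duration_d):
            raise ValueError("endpoint_day must lie within the simulated horizon")
        return self

    def to_setup(self) -> ModelSetup:
        """Materialize the executable model setup from this configuration."""
        tox = {"loss_frac_application": self.toxicant.loss_frac_application}
        if self.toxicant.k_decay is not None:
            tox["k_decay"] = self.toxicant.k_decay
        events = dosing_schedule(
            self.duration_d,
            P_per_event=self.dosing.P_per_event,
            NO3_N_per_event=self.dosing.NO3_N_per_event,
        )
        return ModelSetup(
            geometry=self.geometry,
            params=dict(self.groups),
            decomposition=self.decomposition,
            light=self.light,
            initial=self.initial,
            dose_response=self.dose_response.model_dump(),
            toxicant=tox,
            dosing=events,
            solver=SolverOptions(
                rtol=self.solver.rtol,
                atol=self.solver.atol,
                method=self.solver.method,
                samples_per_day=self.solver.samples_per_day,
            ),
            duration_d=self.duration_d,
        )


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    ``None`` or an empty file yields the all-defaults configuration.
    Validation errors name the offending key and constraint.
    """
    if path is None:
        return RunConfig()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    try:
        return RunConfig(**raw)
    except ValidationError as exc:
        locs = "; ".join(
            ".".join(str(p) for p in err["loc"]) + ": " + err["msg"]
            for err in exc.errors()
        )
        raise ValueError(f"invalid configuration ({path}): {locs}") from exc


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Write a configuration back to YAML (round-trips through load)."""
    Path(path).write_text(
        yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True)
    )


def config_hash(config: RunConfig) -> str:
    """Stable hash identifying a configuration (for run manifests)."""
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
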