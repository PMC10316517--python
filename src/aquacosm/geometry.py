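"""Microcosm vessel geometry and light climate at the surface."""

from __future__ import annotations

import math

from pydantic import BaseModel, ConfigDict, model_validator


class MicrocosmGeometry(BaseModel):
    """Dimensions and surface light of one cylindrical microcosm.

    Defaults describe an 8 L glass vase of 25 cm diameter with three
    periphyton strips (150 cm^2 each) attached to the wall, lit at a mean
    surface irradiance of 77.2 umol photons m^-2 s^-1 on a 16h:8h
    light:dark cycle.

    Attributes
    ----------
    V : water volume (m^3)
    H : water height (m)
    A_peri : colonizable wall area for periphyton (m^2)
    A_sed : sediment surface area (m^2)
    A_strip : total sampled strip area, a reporting subarea of A_peri (m^2)
    I_surface : surface irradiance (umol photons m^-2 s^-1)
    photoperiod : lit fraction of the day, in (0, 1]
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    V: float = 0.008
    H: float = 0.008 / (math.pi * 0.125**2)
    A_peri: float = math.pi * 0.25 * 0.008 / (math.pi * 0.125**2)
    A_sed: float = math.pi * 0.125**2
    A_strip: float = 3 * 150e-4
    I_surface: float = 77.2
    photoperiod: float = 16 / 24

    @model_validator(mode="after")
    def _check(self) -> "MicrocosmGeometry":
        for name in ("V", "H", "A_peri", "A_sed", "A_strip", "I_surface"):
            if not getattr(self, name) > 0:
                raise ValueError(f"geometry field {name} must be strictly positive")
        if not (0 < self.photoperiod <= 1):
            raise ValueError("photoperiod must lie in (0, 1]")
        return self

    @classmethod
    def cylinder(
        cls,
        volume_m3: float = 0.008,
        diameter_m: float = 0.25,
        strip_area_m2: float = 3 * 150e-4,
        I_surface: float = 77.2,
        photoperiod: float = 16 / 24,
    ) -> "MicrocosmGeometry":
        """Build geometry for a water cylinder of given volume and diameter.

        The wall area available to periphyton is the wetted lateral surface
        pi * d * H with H = V / A_sed.
        """
        if volume_m3 <= 0 or diameter_m <= 0:
            raise ValueError("volume and diameter must be strictly positive")
        a_sed = math.pi * (diameter_m / 2) ** 2
        h = volume_m3 / a_sed
        return cls(
            V=volume_m3,
            H=h,
            A_sed=a_sed,
            A_peri=math.pi * diameter_m * h,
            A_strip=strip_area_m2,
            I_surface=I_surface,
            photoperiod=photoperiod,
        )

    @property
    def mean_irradiance(self) -> float:
        """Photoperiod-averaged surface irradiance (umol m^-2 s^-1)."""
        return self.I_surface * self.photoperiod
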