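"""The evaluative regional environment.

Geometry, phase composition and transport parameters of the hypothetical
100 000 km^2 region (90% land, 10% water with underlying sediment) in which
all fate simulations run.  Only area and land/water split are fixed by the
study design; everything else is an EQC-style temperate-North-America
default and ships in an editable YAML file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

__all__ = ["EvaluativeEnvironment", "EnvironmentError_", "load_environment"]


class EnvironmentError_(ValueError):
    """Invalid evaluative-environment configuration."""


@dataclass(frozen=True)
class EvaluativeEnvironment:
    total_area: float = 1.0e11
    water_area_fraction: float = 0.10
    air_height: float = 1000.0
    water_depth: float = 20.0
    soil_depth: float = 0.1
    sediment_depth: float = 0.01
    temperature: float = 298.15

    vf_aerosol: float = 2.0e-11
    vf_susp_solids: float = 5.0e-6
    vf_biota: float = 1.0e-6
    vf_soil_air: float = 0.2
    vf_soil_water: float = 0.3
    vf_soil_solids: float = 0.5
    vf_sed_water: float = 0.8
    vf_sed_solids: float = 0.2

    foc_soil: float = 0.02
    foc_sediment: float = 0.04
    foc_susp: float = 0.2
    lipid_biota: float = 0.05
    fom_aerosol: float = 0.2

    rho_solids: float = 2400.0
    rho_water: float = 1000.0
    rho_biota: float = 1000.0
    rho_aerosol: float = 2000.0

    tau_air: float = 100.0
    tau_water: float = 1000.0

    rain_rate: float = 9.7e-5
    scavenging_ratio: float = 200000.0
    dry_dep_velocity: float = 10.8
    mtc_air_side: float = 5.0
    mtc_water_side: float = 0.05
    mtc_soil_air: float = 0.02
    mtc_soil_water: float = 1.0e-5
    mtc_sed_water: float = 1.0e-4
    runoff_water: float = 3.9e-5
    runoff_solids: float = 2.3e-8
    sed_deposition: float = 4.6e-8
    sed_resuspension: float = 1.1e-8
    sed_burial: float = 3.4e-8

    leaf_area_index: float = 2.0
    foliage_volume_per_area: float = 5.0e-4
    lipid_foliage: float = 0.02
    mtc_foliage: float = 9.0
    foliage_loss_rate: float = 1.0e-3
    particle_interception: float = 0.2
    rho_foliage: float = 900.0

    rcf_a: float = 0.82
    rcf_b: float = 0.03
    rcf_c: float = 0.77

    def __post_init__(self):
        if not 0.0 < self.water_area_fraction < 1.0:
            raise EnvironmentError_(
                f"water_area_fraction must be in (0,1), got {self.water_area_fraction}"
            )
        for fld in ("total_area", "air_height", "water_depth", "soil_depth",
                    "sediment_depth", "temperature", "tau_air", "tau_water",
                    "rho_solids", "rho_water", "rho_biota", "rho_aerosol"):
            if not getattr(self, fld) > 0:
                raise EnvironmentError_(f"{fld} must be positive")
        for fld in ("vf_aerosol", "vf_susp_solids", "vf_biota", "rain_rate",
                    "scavenging_ratio", "dry_dep_velocity", "mtc_air_side",
                    "mtc_water_side", "mtc_soil_air", "mtc_soil_water",
                    "mtc_sed_water", "runoff_water", "runoff_solids",
                    "sed_deposition", "sed_resuspension", "sed_burial"):
            if getattr(self, fld) < 0:
                raise EnvironmentError_(f"{fld} must be >= 0")
        if self.vf_soil_air + self.vf_soil_water + self.vf_soil_solids > 1.0 + 1e-12:
            raise EnvironmentError_("soil phase volume fractions exceed 1")
        if self.vf_sed_water + self.vf_sed_solids > 1.0 + 1e-12:
            raise EnvironmentError_("sediment phase volume fractions exceed 1")

    # -- derived geometry -------------------------------------------------
    @property
    def area_water(self) -> float:
        return self.total_area * self.water_area_fraction

    @property
    def area_soil(self) -> float:
        return self.total_area * (1.0 - self.water_area_fraction)

    @property
    def volume_air(self) -> float:
        return self.total_area * self.air_height

    @property
    def volume_water(self) -> float:
        return self.area_water * self.water_depth

    @property
    def volume_soil(self) -> float:
        return self.area_soil * self.soil_depth

    @property
    def volume_sediment(self) -> float:
        return self.area_water * self.sediment_depth

    def replace(self, **changes) -> "EvaluativeEnvironment":
        return dataclasses.replace(self, **changes)


def load_environment(path: str | Path | None = None, **overrides) -> EvaluativeEnvironment:
    """Load the evaluative environment from YAML (shipped default if no path)."""
    if path is None:
        text = resources.files("fugrisk.data").joinpath("environment.yaml").read_text()
    else:
        text = Path(path).read_text()
    cfg = yaml.safe_load(text) or {}
    known = {f.name for f in dataclasses.fields(EvaluativeEnvironment)}
    unknown = set(cfg) - known
    if unknown:
        raise EnvironmentError_(f"unknown environment key(s): {sorted(unknown)}")
    cfg.update(overrides)
    return EvaluativeEnvironment(**{k: float(v) for k, v in cfg.items()})
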