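"""Steady-state (Level III) fugacity mass balance for the evaluative region.

Four bulk compartments — air, water, soil, sediment — exchange chemical via
standard intermedia D values (two-film diffusion, rain dissolution, wet/dry
particle deposition, runoff, sediment deposition/resuspension) and lose it
by first-order reaction, advective outflow of air and water, and sediment
burial.  The balance is linear in fugacity:

    E_i + sum_j D_ji f_j = f_i (D_R,i + D_A,i + D_B,i + sum_j D_ij)

with zero-inflow boundary (no chemical enters from adjacent regions).  The
4x4 system is solved directly.  Internal units: amounts mol, rates mol/h,
fugacity Pa, capacities mol/(m^3 Pa), conductances mol/(Pa h); conversion to
kg and mg/L only at the reporting boundary.

Vegetation (foliage + root crop) is a receiving sub-model in steady state
with air and soil; it does not feed back on the four-compartment balance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .environment import EvaluativeEnvironment
from .inventory import EmissionScenario
from .properties import ChemicalRecord, derived_partition_coefficients

__all__ = [
    "AIR", "WATER", "SOIL", "SEDIMENT", "COMPARTMENTS",
    "R_GAS", "Capacities", "TransportCoefficients", "FateResult",
    "VegetationExposure", "MediaConcentrations", "FateError",
    "compute_capacities", "compute_transport_coefficients",
    "solve_steady_state", "vegetation_exposure", "media_concentrations",
]

R_GAS = 8.314  # Pa m^3 / (mol K)

AIR, WATER, SOIL, SEDIMENT = 0, 1, 2, 3
COMPARTMENTS = ("air", "water", "soil", "sediment")


class FateError(RuntimeError):
    """No steady state exists or the inputs are unusable."""


@dataclass(frozen=True)
class Capacities:
    """Fugacity capacities (Z values), mol/(m^3 Pa)."""

    z_air_pure: float
    z_water_pure: float
    z_aerosol: float
    z_susp_solids: float
    z_biota: float
    z_soil_solids: float
    z_sed_solids: float
    z_foliage: float
    bulk: np.ndarray  # shape (4,): bulk Z of air, water, soil, sediment


def compute_capacities(
    chem: ChemicalRecord, env: EvaluativeEnvironment, c_oc: float = 0.35
) -> Capacities:
    """Per-phase and bulk fugacity capacities for one chemical.

    Z_air = 1/RT; Z_water = Z_air/KAW; sorbed solids from KOC and the phase
    organic-carbon fraction; aerosol from a KOA-proportional rule; biota
    from KOW with a lipid fraction.  Bulk Z is the volume-fraction-weighted
    sum of phase Z.
    """
    kaw = chem.kaw
    if not (math.isfinite(kaw) and kaw > 0):
        raise FateError(f"non-finite or non-positive KAW for {chem.substance_id}")
    z_air = 1.0 / (R_GAS * env.temperature)
    z_water = z_air / kaw
    dc = derived_partition_coefficients(chem, c_oc=c_oc)
    # solids: Z = Z_water * Kp * rho/1000, Kp = foc*KOC in L/kg
    def z_solid(foc: float) -> float:
        return z_water * foc * dc.koc * env.rho_solids / 1000.0

    z_soil_solids = z_solid(env.foc_soil)
    z_sed_solids = z_solid(env.foc_sediment)
    z_susp = z_water * env.foc_susp * dc.koc * env.rho_solids / 1000.0
    z_biota = z_water * env.lipid_biota * chem.kow * env.rho_biota / 1000.0
    z_aerosol = z_air * dc.koa * env.fom_aerosol
    z_foliage = z_air * dc.koa * env.lipid_foliage

    bulk = np.array([
        (1.0 - env.vf_aerosol) * z_air + env.vf_aerosol * z_aerosol,
        (1.0 - env.vf_susp_solids - env.vf_biota) * z_water
        + env.vf_susp_solids * z_susp + env.vf_biota * z_biota,
        env.vf_soil_air * z_air + env.vf_soil_water * z_water
        + env.vf_soil_solids * z_soil_solids,
        env.vf_sed_water * z_water + env.vf_sed_solids * z_sed_solids,
    ])
    return Capacities(
        z_air_pure=z_air, z_water_pure=z_water, z_aerosol=z_aerosol,
        z_susp_solids=z_susp, z_biota=z_biota, z_soil_solids=z_soil_solids,
        z_sed_solids=z_sed_solids, z_foliage=z_foliage, bulk=bulk,
    )


@dataclass
class TransportCoefficients:
    """Reaction, advection, burial and intermedia D values, mol/(Pa h).

    ``d_inter[i, j]`` is the one-way conductance from compartment i to j;
    structurally one-directional processes (particle deposition, runoff,
    burial) appear only in their forward direction.
    """

    d_reaction: np.ndarray  # (4,)
    d_advection: np.ndarray  # (4,) — nonzero for air and water only
    d_burial: float  # sediment burial
    d_inter: np.ndarray  # (4, 4), zero diagonal

    def total_loss(self) -> np.ndarray:
        """Diagonal of the balance matrix: all losses out of each compartment."""
        out = self.d_reaction + self.d_advection + self.d_inter.sum(axis=1)
        out[SEDIMENT] += self.d_burial
        return out


def compute_transport_coefficients(
    chem: ChemicalRecord, env: EvaluativeEnvironment, z: Capacities
) -> TransportCoefficients:
    """Standard Level III D values for one chemical in the region."""
    volumes = np.array([env.volume_air, env.volume_water,
                        env.volume_soil, env.volume_sediment])
    half_lives = np.array([chem.hl_air, chem.hl_water, chem.hl_soil, chem.hl_sediment])
    k_react = math.log(2.0) / half_lives
    d_reaction = volumes * z.bulk * k_react

    d_advection = np.zeros(4)
    d_advection[AIR] = volumes[AIR] * z.bulk[AIR] / env.tau_air
    d_advection[WATER] = volumes[WATER] * z.bulk[WATER] / env.tau_water

    a_w, a_s = env.area_water, env.area_soil
    # air-water: two-film diffusion + rain dissolution + wet/dry particle dep
    d_vw = a_w / (1.0 / (env.mtc_air_side * z.z_air_pure)
                  + 1.0 / (env.mtc_water_side * z.z_water_pure))
    d_rain_w = a_w * env.rain_rate * z.z_water_pure
    d_wet_w = a_w * env.rain_rate * env.scavenging_ratio * env.vf_aerosol * z.z_aerosol
    d_dry_w = a_w * env.dry_dep_velocity * env.vf_aerosol * z.z_aerosol

    # air-soil: boundary-layer + in-soil diffusion in series, plus deposition
    d_bl = a_s * env.mtc_air_side * z.z_air_pure
    d_soil_air = a_s * env.mtc_soil_air * z.z_air_pure
    d_soil_water = a_s * env.mtc_soil_water * z.z_water_pure
    d_vs = 1.0 / (1.0 / d_bl + 1.0 / (d_soil_air + d_soil_water))
    d_rain_s = a_s * env.rain_rate * z.z_water_pure
    d_wet_s = a_s * env.rain_rate * env.scavenging_ratio * env.vf_aerosol * z.z_aerosol
    d_dry_s = a_s * env.dry_dep_velocity * env.vf_aerosol * z.z_aerosol

    # soil -> water runoff (water + solids), one-way
    d_runoff = a_s * (env.runoff_water * z.z_water_pure
                      + env.runoff_solids * z.z_soil_solids)

    # water <-> sediment
    d_diff_ws = a_w * env.mtc_sed_water * z.z_water_pure
    d_dep = a_w * env.sed_deposition * z.z_susp_solids
    d_res = a_w * env.sed_resuspension * z.z_sed_solids
    d_burial = a_w * env.sed_burial * z.z_sed_solids

    d_inter = np.zeros((4, 4))
    d_inter[AIR, WATER] = d_vw + d_rain_w + d_wet_w + d_dry_w
    d_inter[WATER, AIR] = d_vw
    d_inter[AIR, SOIL] = d_vs + d_rain_s + d_wet_s + d_dry_s
    d_inter[SOIL, AIR] = d_vs
    d_inter[SOIL, WATER] = d_runoff
    d_inter[WATER, SEDIMENT] = d_diff_ws + d_dep
    d_inter[SEDIMENT, WATER] = d_diff_ws + d_res

    return TransportCoefficients(
        d_reaction=d_reaction, d_advection=d_advection,
        d_burial=d_burial, d_inter=d_inter,
    )


@dataclass
class FateResult:
    """Steady-state fate of one substance under one emission scenario."""

    substance_id: str
    emission_mol_h: np.ndarray  # (4,) mol/h into each compartment
    fugacities: np.ndarray  # (4,) Pa
    conc_mol_m3: np.ndarray  # (4,) bulk mol/m^3
    conc_mg_l: np.ndarray  # (4,) bulk mg/L
    mass_kg: np.ndarray  # (4,)
    mass_fraction_pct: np.ndarray  # (4,), sums to 100 when mass > 0
    p_ov_reaction_h: float  # overall reaction residence time (nan at E=0)
    residence_time_overall_h: float  # incl. advection and burial (nan at E=0)
    loss_budget_kg_h: dict = field(default_factory=dict)
    capacities: Capacities | None = None
    transport: TransportCoefficients | None = None

    @property
    def p_ov_reaction_days(self) -> float:
        return self.p_ov_reaction_h / 24.0


def balance_matrix(t: TransportCoefficients) -> np.ndarray:
    """Assemble the 4x4 Level III balance matrix A with A f = E."""
    a = np.diag(t.total_loss())
    a -= t.d_inter.T
    return a


def solve_steady_state(
    chem: ChemicalRecord,
    env: EvaluativeEnvironment,
    scenario: EmissionScenario,
    z: Capacities | None = None,
    transport: TransportCoefficients | None = None,
    c_oc: float = 0.35,
) -> FateResult:
    """Solve the Level III balance for one chemical and emission scenario.

    ``transport`` may be supplied to run with modified D values (e.g. for
    limiting-case analyses); by default it is computed from chem and env.
    """
    if z is None:
        z = compute_capacities(chem, env, c_oc=c_oc)
    if transport is None:
        transport = compute_transport_coefficients(chem, env, z)

    e_kg_h = np.array(scenario.moe_fractions) * scenario.total_rate
    e_mol_h = np.zeros(4)
    e_mol_h[:3] = e_kg_h * 1000.0 / chem.molar_mass  # air, water, soil

    volumes = np.array([env.volume_air, env.volume_water,
                        env.volume_soil, env.volume_sediment])

    if scenario.total_rate == 0.0:
        zero = np.zeros(4)
        return FateResult(
            substance_id=chem.substance_id, emission_mol_h=e_mol_h,
            fugacities=zero, conc_mol_m3=zero.copy(), conc_mg_l=zero.copy(),
            mass_kg=zero.copy(), mass_fraction_pct=zero.copy(),
            p_ov_reaction_h=float("nan"), residence_time_overall_h=float("nan"),
            loss_budget_kg_h={k: 0.0 for k in _loss_keys()},
            capacities=z, transport=transport,
        )

    a = balance_matrix(transport)
    try:
        f = np.linalg.solve(a, e_mol_h)
    except np.linalg.LinAlgError:
        raise FateError(
            f"no steady state for {chem.substance_id}: singular balance "
            "(a reachable compartment has no loss pathway)"
        ) from None
    if not np.all(np.isfinite(f)) or np.any(f < -1e-12 * max(abs(f).max(), 1.0)):
        raise FateError(
            f"no physical steady state for {chem.substance_id}: "
            f"fugacities {f}"
        )
    f = np.clip(f, 0.0, None)

    conc = z.bulk * f  # mol/m^3 bulk
    mass_mol = volumes * conc
    mass_kg = mass_mol * chem.molar_mass / 1000.0
    total_mass = mass_kg.sum()
    mass_frac = 100.0 * mass_kg / total_mass if total_mass > 0 else np.zeros(4)
    conc_mg_l = conc * chem.molar_mass  # mol/m^3 * g/mol = g/m^3 = mg/L

    to_kg = chem.molar_mass / 1000.0
    react_mol = transport.d_reaction * f
    adv_mol = transport.d_advection * f
    burial_mol = transport.d_burial * f[SEDIMENT]
    loss_budget = {}
    for i, name in enumerate(COMPARTMENTS):
        loss_budget[f"reaction_{name}"] = react_mol[i] * to_kg
    loss_budget["advection_air"] = adv_mol[AIR] * to_kg
    loss_budget["advection_water"] = adv_mol[WATER] * to_kg
    loss_budget["sediment_burial"] = burial_mol * to_kg

    react_total = react_mol.sum()
    loss_total = react_total + adv_mol.sum() + burial_mol
    p_ov = mass_mol.sum() / react_total if react_total > 0 else float("inf")
    tau_ov = mass_mol.sum() / loss_total if loss_total > 0 else float("inf")

    return FateResult(
        substance_id=chem.substance_id, emission_mol_h=e_mol_h,
        fugacities=f, conc_mol_m3=conc, conc_mg_l=conc_mg_l,
        mass_kg=mass_kg, mass_fraction_pct=mass_frac,
        p_ov_reaction_h=p_ov, residence_time_overall_h=tau_ov,
        loss_budget_kg_h=loss_budget, capacities=z, transport=transport,
    )


def _loss_keys():
    return [f"reaction_{n}" for n in COMPARTMENTS] + [
        "advection_air", "advection_water", "sediment_burial"
    ]


@dataclass(frozen=True)
class VegetationExposure:
    """Steady-state foliage and root-crop concentrations."""

    foliage_mol_m3: float
    foliage_mg_kg: float
    foliage_mol_kg: float
    root_mol_kg: float
    root_mg_kg: float


def vegetation_exposure(
    chem: ChemicalRecord,
    env: EvaluativeEnvironment,
    fate: FateResult,
    *,
    disable_particles: bool = False,
    disable_loss: bool = False,
) -> VegetationExposure:
    """Foliage and root-crop exposure driven by the solved fate field.

    Foliage exchanges gas with bulk air (KOA-scaled capacity) and intercepts
    a fraction of the particle-bound deposition flux, against a first-order
    foliage loss (growth dilution, cuticle erosion).  Root crop is at
    equilibrium with soil pore water scaled by a KOW-based root
    concentration factor.
    """
    z = fate.capacities
    assert z is not None
    f_air = fate.fugacities[AIR]
    f_soil = fate.fugacities[SOIL]

    a_fol = env.area_soil * env.leaf_area_index
    v_fol = env.area_soil * env.foliage_volume_per_area
    d_gas = a_fol * env.mtc_foliage * z.z_air_pure
    d_part = 0.0
    if not disable_particles:
        d_part = (env.area_soil * env.particle_interception
                  * (env.rain_rate * env.scavenging_ratio + env.dry_dep_velocity)
                  * env.vf_aerosol * z.z_aerosol)
    d_loss = 0.0 if disable_loss else v_fol * z.z_foliage * env.foliage_loss_rate
    f_fol = (d_gas + d_part) * f_air / (d_gas + d_loss) if (d_gas + d_loss) > 0 else 0.0
    c_fol = z.z_foliage * f_fol  # mol/m^3
    c_fol_mol_kg = c_fol / env.rho_foliage
    c_fol_mg_kg = c_fol_mol_kg * chem.molar_mass * 1000.0

    rcf = env.rcf_a + env.rcf_b * chem.kow ** env.rcf_c  # L/kg
    c_pore_mol_l = z.z_water_pure * f_soil / 1000.0
    c_root_mol_kg = rcf * c_pore_mol_l
    c_root_mg_kg = c_root_mol_kg * chem.molar_mass * 1000.0

    return VegetationExposure(
        foliage_mol_m3=c_fol, foliage_mg_kg=c_fol_mg_kg,
        foliage_mol_kg=c_fol_mol_kg,
        root_mol_kg=c_root_mol_kg, root_mg_kg=c_root_mg_kg,
    )


@dataclass(frozen=True)
class MediaConcentrations:
    """Exposure-medium concentrations handed to the bioaccumulation stage."""

    c_air_gas_mol_m3: float
    c_water_diss_mol_l: float
    c_soil_solids_mol_kg: float
    c_sed_solids_mol_kg: float
    c_pore_water_mol_l: float
    c_foliage_mol_kg: float
    c_root_mol_kg: float

    def item(self, name: str) -> float:
        return {
            "air": self.c_air_gas_mol_m3,
            "water": self.c_water_diss_mol_l,
            "soil": self.c_soil_solids_mol_kg,
            "sediment": self.c_sed_solids_mol_kg,
            "foliage": self.c_foliage_mol_kg,
            "root_crop": self.c_root_mol_kg,
        }[name]


def media_concentrations(
    chem: ChemicalRecord,
    env: EvaluativeEnvironment,
    fate: FateResult,
    veg: VegetationExposure | None = None,
) -> MediaConcentrations:
    """Assemble the exposure media from a solved fate field."""
    z = fate.capacities
    assert z is not None
    if veg is None:
        veg = vegetation_exposure(chem, env, fate)
    f = fate.fugacities
    return MediaConcentrations(
        c_air_gas_mol_m3=z.z_air_pure * f[AIR],
        c_water_diss_mol_l=z.z_water_pure * f[WATER] / 1000.0,
        c_soil_solids_mol_kg=z.z_soil_solids * f[SOIL] / env.rho_solids,
        c_sed_solids_mol_kg=z.z_sed_solids * f[SEDIMENT] / env.rho_solids,
        c_pore_water_mol_l=z.z_water_pure * f[SOIL] / 1000.0,
        c_foliage_mol_kg=veg.foliage_mol_kg,
        c_root_mol_kg=veg.root_mol_kg,
    )
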