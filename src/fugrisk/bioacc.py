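"""Food-web bioaccumulation: one-compartment toxicokinetic receptor models.

Each vertebrate/invertebrate receptor is a steady-state one-compartment
model.  Uptake: respiratory (efficiency x ventilation x medium
concentration), dietary (gut efficiency x feeding rate x diet-weighted
prey/plant/soil concentrations) and drinking water for air-breathers.
Losses: respiratory elimination (uptake clearance over the body-medium
partition ratio), fecal egestion, urinary excretion (air-breathers),
biotransformation (allometrically scaled from the reference-mass half-life),
growth dilution, and special first-order losses (lactation for the dairy
cow, egg production for the laying hen).  Autotroph receptors (foliage,
root crop) take their concentration directly from the fate stage's
vegetation sub-model.

The diet matrix links receptors into a food web evaluated in trophic
(topological) order; all balances are linear, so the trophic-ordered sweep
is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from graphlib import CycleError, TopologicalSorter
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .fate import MediaConcentrations
from .properties import ChemicalRecord

__all__ = [
    "Receptor", "ReceptorResult", "BioaccParams", "BioaccError",
    "scale_biotransformation", "receptor_steady_state", "solve_food_web",
    "load_roster", "MEDIA_DIET_ITEMS", "ALLOMETRIC_EXPONENT",
    "REFERENCE_MASS_AQUATIC", "REFERENCE_MASS_AIRBREATHER",
]

TAXA = ("autotroph", "aquatic_invertebrate", "fish", "bird", "mammal", "human")
MEDIA_DIET_ITEMS = ("soil", "sediment", "foliage", "root_crop")

#: Reference body masses (kg) at which biotransformation half-lives are given.
REFERENCE_MASS_AQUATIC = 0.01
REFERENCE_MASS_AIRBREATHER = 70.0

#: Allometric exponent on the biotransformation rate constant.
ALLOMETRIC_EXPONENT = -0.25


class BioaccError(RuntimeError):
    """Invalid receptor roster or unsolvable food web."""


@dataclass(frozen=True)
class BioaccParams:
    """Global toxicokinetic constants shared by the roster."""

    egestion_factor: float = 0.25
    urinary_clearance: float = 0.0012  # L/kg/h
    gut_ed_a: float = 3.0e-7
    gut_ed_b: float = 2.0
    resp_eff_water: float = 0.8
    resp_eff_air: float = 0.7
    body_water_fraction: float = 0.7
    body_density: float = 1000.0  # kg/m^3


@dataclass(frozen=True)
class Receptor:
    """One representative organism of the evaluative food web."""

    receptor_id: str
    taxon_class: str
    habitat: str = "terrestrial"
    body_mass: float = 1.0  # kg
    lipid_fraction: float = 0.05
    respiration_medium: str = "water"  # water | air
    ventilation_rate: float = 0.0  # L/kg/h (water) or m^3/kg/h (air)
    feeding_rate: float = 0.0  # kg food / kg body / day
    water_ingestion: float = 0.0  # L/kg/day, air-breathers
    diet: Mapping[str, float] = field(default_factory=dict)
    growth_rate_constant: float = 0.0  # 1/h
    special_loss_rate: float = 0.0  # 1/h (lactation, egg production)
    media_source: str | None = None  # autotrophs: which medium they are
    population_biomass: float = 0.0  # kg in the region (exposure metric)

    def __post_init__(self):
        if self.taxon_class not in TAXA:
            raise BioaccError(f"unknown taxon_class {self.taxon_class!r}")
        if self.taxon_class != "autotroph":
            if not self.body_mass > 0:
                raise BioaccError(f"{self.receptor_id}: body_mass must be > 0")
            if not 0.0 < self.lipid_fraction < 1.0:
                raise BioaccError(f"{self.receptor_id}: lipid_fraction must be in (0,1)")
            if self.respiration_medium not in ("water", "air"):
                raise BioaccError(f"{self.receptor_id}: bad respiration_medium")
            if self.diet:
                s = sum(self.diet.values())
                if abs(s - 1.0) > 1e-9:
                    raise BioaccError(
                        f"{self.receptor_id}: diet fractions sum to {s}, expected 1"
                    )


@dataclass(frozen=True)
class ReceptorResult:
    """Steady-state exposure of one receptor to one chemical."""

    receptor_id: str
    conc_mol_kg: float  # whole-body
    conc_mmol_l: float  # whole-body, volumetric
    conc_mg_kg: float  # wet weight
    intake_mg_kg_day: float | None  # air-breathers (incl. human), else None
    baf_l_kg: float  # vs respiration medium (m^3/kg for air-breathers)


def scale_biotransformation(chem: ChemicalRecord, receptor: Receptor) -> float:
    """First-order biotransformation rate constant (1/h) for a receptor.

    The whole-body half-life at the taxon's reference mass is rescaled
    allometrically: k_B = (ln 2 / HL_ref) * (m / m_ref)^(-1/4), so at the
    reference mass the reference half-life is recovered exactly.
    """
    if receptor.taxon_class == "autotroph":
        return 0.0
    if receptor.taxon_class in ("aquatic_invertebrate", "fish"):
        hl_ref, m_ref = chem.hl_biotrans_aquatic, REFERENCE_MASS_AQUATIC
    else:
        hl_ref, m_ref = chem.hl_biotrans_airbreather, REFERENCE_MASS_AIRBREATHER
    if hl_ref == 0.0:
        return float("inf")
    return (math.log(2.0) / hl_ref) * (receptor.body_mass / m_ref) ** ALLOMETRIC_EXPONENT


def _gut_efficiency(kow: float, params: BioaccParams) -> float:
    return 1.0 / (params.gut_ed_a * kow + params.gut_ed_b)


def receptor_steady_state(
    chem: ChemicalRecord,
    receptor: Receptor,
    media: MediaConcentrations,
    prey: Mapping[str, ReceptorResult] | None = None,
    params: BioaccParams | None = None,
) -> ReceptorResult:
    """Solve one receptor's steady-state mass balance.

    All prey receptors named in the diet must already be solved; media diet
    items (soil, sediment, foliage, root_crop) come from ``media``.
    """
    params = params or BioaccParams()
    prey = prey or {}

    if receptor.taxon_class == "autotroph":
        src = receptor.media_source or receptor.receptor_id
        c = media.item(src)
        return _result(receptor, chem, params, c, intake=None, baf=0.0)

    kow = chem.kow
    k_bw = receptor.lipid_fraction * kow + params.body_water_fraction  # L/kg

    if receptor.respiration_medium == "water":
        c_medium = media.c_water_diss_mol_l
        uptake_resp = params.resp_eff_water * receptor.ventilation_rate * c_medium
        k_resp = params.resp_eff_water * receptor.ventilation_rate / k_bw
        drink = 0.0
        k_urin = 0.0
    else:
        c_medium = media.c_air_gas_mol_m3
        uptake_resp = params.resp_eff_air * receptor.ventilation_rate * c_medium
        k_ba = k_bw / (1000.0 * chem.kaw)  # m^3/kg
        k_resp = params.resp_eff_air * receptor.ventilation_rate / k_ba
        drink = receptor.water_ingestion / 24.0 * media.c_water_diss_mol_l
        k_urin = params.urinary_clearance / k_bw

    e_d = _gut_efficiency(kow, params)
    g_d = receptor.feeding_rate / 24.0  # kg/kg/h
    c_diet = 0.0
    for item, frac in receptor.diet.items():
        if item in MEDIA_DIET_ITEMS:
            c_item = media.item(item)
        elif item in prey:
            c_item = prey[item].conc_mol_kg
        else:
            raise BioaccError(
                f"{receptor.receptor_id}: diet item {item!r} is neither a medium "
                f"({MEDIA_DIET_ITEMS}) nor a solved prey receptor"
            )
        c_diet += frac * c_item
    uptake_diet = e_d * g_d * c_diet
    k_egest = params.egestion_factor * e_d * g_d

    k_bio = scale_biotransformation(chem, receptor)
    k_total = (k_resp + k_urin + k_egest + k_bio
               + receptor.growth_rate_constant + receptor.special_loss_rate)
    if not k_total > 0:
        raise BioaccError(f"{receptor.receptor_id}: no elimination pathway; "
                          "steady state undefined")
    uptake = uptake_resp + uptake_diet + drink
    c_body = 0.0 if math.isinf(k_total) else uptake / k_total

    intake = None
    if receptor.respiration_medium == "air":
        intake = uptake * chem.molar_mass * 1000.0 * 24.0  # mg/kg/day absorbed
    baf = c_body / c_medium if c_medium > 0 else 0.0
    return _result(receptor, chem, params, c_body, intake=intake, baf=baf)


def _result(receptor, chem, params, c_mol_kg, intake, baf) -> ReceptorResult:
    rho_l = params.body_density / 1000.0  # kg/L
    return ReceptorResult(
        receptor_id=receptor.receptor_id,
        conc_mol_kg=c_mol_kg,
        conc_mmol_l=c_mol_kg * rho_l * 1000.0,
        conc_mg_kg=c_mol_kg * chem.molar_mass * 1000.0,
        intake_mg_kg_day=intake,
        baf_l_kg=baf,
    )


def solve_food_web(
    chem: ChemicalRecord,
    roster: list[Receptor],
    media: MediaConcentrations,
    params: BioaccParams | None = None,
) -> dict[str, ReceptorResult]:
    """Evaluate the whole roster in trophic (topological) order.

    The diet graph must be acyclic; a cycle raises :class:`BioaccError`
    naming the receptors involved.
    """
    params = params or BioaccParams()
    by_id = {r.receptor_id: r for r in roster}
    ts: TopologicalSorter = TopologicalSorter()
    for r in roster:
        deps = [d for d in r.diet if d in by_id]
        ts.add(r.receptor_id, *deps)
    try:
        order = list(ts.static_order())
    except CycleError as exc:
        raise BioaccError(f"cyclic diet dependency: {exc.args[1]}") from None
    results: dict[str, ReceptorResult] = {}
    for rid in order:
        results[rid] = receptor_steady_state(chem, by_id[rid], media, results, params)
    # preserve roster order in the returned mapping
    return {r.receptor_id: results[r.receptor_id] for r in roster}


def load_roster(path: str | Path | None = None) -> tuple[list[Receptor], BioaccParams]:
    """Load the receptor roster + diet matrix from YAML (default if no path)."""
    if path is None:
        text = resources.files("fugrisk.data").joinpath("roster.yaml").read_text()
    else:
        text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    # PyYAML 1.1 resolves exponents without a sign (5.0e10) as strings
    def _num(x):
        if isinstance(x, str):
            try:
                return float(x)
            except ValueError:
                return x
        return x

    params = BioaccParams(**{k: _num(v) for k, v in (cfg.get("params") or {}).items()})
    roster = []
    for entry in cfg["receptors"]:
        entry = {k: _num(v) for k, v in entry.items()}
        entry["diet"] = {k: float(v) for k, v in (entry.get("diet") or {}).items()}
        roster.append(Receptor(**entry))
    ids = [r.receptor_id for r in roster]
    if len(set(ids)) != len(ids):
        raise BioaccError("duplicate receptor_id in roster")
    return roster, params
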