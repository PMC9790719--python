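"""Screening metrics: EAF, HAF, per-receptor RCR and RAF.

The exposure assessment factor (EAF) and hazard assessment factor (HAF) are
computed at a unit emission rate of 1 kg/h — they characterize a chemical's
exposure and combined persistence/bioaccumulation/toxicity ("PBT") potential
independent of actual releases.  The risk characterization ratio (RCR) per
receptor, and the risk assessment factor (RAF = highest RCR across
receptors), use actual emission rates.  Concentration-threshold taxa
(autotrophs, aquatic invertebrates, fish) compare whole-body concentration
(mmol/L) against the aquatic effect threshold C_T; intake-threshold taxa
(birds, mammals, human) compare the absorbed intake rate (mg/kg/day)
against the intake-rate threshold IR_T.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .bioacc import BioaccParams, Receptor, ReceptorResult, solve_food_web
from .environment import EvaluativeEnvironment
from .fate import FateResult, media_concentrations, solve_steady_state, vegetation_exposure
from .inventory import EmissionScenario, ScopeKey
from .properties import ChemicalRecord

__all__ = [
    "RiskMetrics", "MetricsError", "UNIT_RATE_KG_H",
    "compute_rcr", "compute_eaf", "compute_haf_raf", "run_receptors",
]

UNIT_RATE_KG_H = 1.0

MOE_CONVENTIONS = ("actual", "air")
_AIR_MOE = (1.0, 0.0, 0.0)


class MetricsError(ValueError):
    """Invalid metric inputs (e.g. non-positive toxicity threshold)."""


@dataclass
class RiskMetrics:
    """The four screening metrics for one substance under one scenario."""

    substance_id: str
    scope_key: ScopeKey | None
    eaf: float
    eaf_receptor: str | None
    haf: float
    haf_receptor: str | None
    rcr: dict[str, float]  # receptor_id -> RCR (defined receptors only)
    raf: float
    most_sensitive_receptor: str | None
    moe_unit: tuple[float, float, float]
    moe_actual: tuple[float, float, float]
    actual_rate_kg_h: float
    p_ov_reaction_days: float
    diagnostics: list[str] = field(default_factory=list)


def run_receptors(
    chem: ChemicalRecord,
    env: EvaluativeEnvironment,
    roster: list[Receptor],
    params: BioaccParams,
    scenario: EmissionScenario,
    c_oc: float = 0.35,
) -> tuple[FateResult, dict[str, ReceptorResult]]:
    """Fate solve + vegetation + food web for one scenario."""
    fate = solve_steady_state(chem, env, scenario, c_oc=c_oc)
    veg = vegetation_exposure(chem, env, fate)
    media = media_concentrations(chem, env, fate, veg)
    return fate, solve_food_web(chem, roster, media, params)


def compute_rcr(
    result: ReceptorResult, receptor: Receptor, chem: ChemicalRecord
) -> float | None:
    """Risk characterization ratio for one receptor, or None if the
    relevant threshold is missing (policy "skip-receptor")."""
    taxon = receptor.taxon_class
    if taxon in ("autotroph", "aquatic_invertebrate", "fish"):
        threshold = {
            "autotroph": chem.c_tox_autotroph,
            "aquatic_invertebrate": chem.c_tox_invertebrate,
            "fish": chem.c_tox_fish,
        }[taxon]
        if threshold is None:
            return None
        if not threshold > 0:
            raise MetricsError(
                f"toxicity threshold for {receptor.receptor_id} must be > 0"
            )
        return result.conc_mmol_l / threshold
    # birds, mammals, human: intake-rate threshold
    if chem.ir_threshold is None:
        return None
    if not chem.ir_threshold > 0:
        raise MetricsError(f"ir_threshold must be > 0, got {chem.ir_threshold}")
    intake = result.intake_mg_kg_day or 0.0
    return intake / chem.ir_threshold


def _argmax_roster_order(values: dict[str, float], roster: list[Receptor]):
    """Max value + attaining receptor; ties resolved by roster order."""
    best_id, best = None, None
    for r in roster:
        v = values.get(r.receptor_id)
        if v is None:
            continue
        if best is None or v > best:
            best, best_id = v, r.receptor_id
    return best, best_id


def compute_eaf(
    chem: ChemicalRecord,
    env: EvaluativeEnvironment,
    roster: list[Receptor],
    params: BioaccParams,
    moe: tuple[float, float, float],
    *,
    norm_kg: float = 1.0,
    c_oc: float = 0.35,
):
    """Exposure assessment factor at unit emission (1 kg/h) under ``moe``.

    EAF_i = steady-state chemical mass in receptor i's population biomass
    per unit emission, over a fixed normalization mass (default 1 kg);
    rankings are invariant to the normalization.  Returns
    (EAF, attaining receptor, per-receptor map, fate result, receptor map).
    """
    scenario = EmissionScenario(chem.substance_id, UNIT_RATE_KG_H, tuple(moe))
    fate, results = run_receptors(chem, env, roster, params, scenario, c_oc)
    per = {}
    for r in roster:
        if r.population_biomass <= 0:
            continue
        mass_kg = (results[r.receptor_id].conc_mol_kg * r.population_biomass
                   * chem.molar_mass / 1000.0)
        per[r.receptor_id] = mass_kg / norm_kg
    eaf, rid = _argmax_roster_order(per, roster)
    return (eaf or 0.0), rid, per, fate, results


def compute_haf_raf(
    chem: ChemicalRecord,
    env: EvaluativeEnvironment,
    roster: list[Receptor],
    params: BioaccParams,
    scenario: EmissionScenario,
    *,
    moe_convention: str = "actual",
    eaf_norm_kg: float = 1.0,
    c_oc: float = 0.35,
) -> RiskMetrics:
    """All four metrics for one substance and one actual-emission scenario.

    EAF and HAF use a unit 1 kg/h emission whose MOE follows
    ``moe_convention``: "actual" uses the scenario's own MOE when its rate
    is positive (keeping RAF = HAF x E exact), "air" forces 100% air.
    """
    if moe_convention not in MOE_CONVENTIONS:
        raise MetricsError(f"unknown MOE convention {moe_convention!r}")
    if moe_convention == "actual" and scenario.total_rate > 0:
        moe_unit = tuple(scenario.moe_fractions)
    else:
        moe_unit = _AIR_MOE

    diagnostics: list[str] = []
    eaf, eaf_rid, _, unit_fate, unit_results = compute_eaf(
        chem, env, roster, params, moe_unit, norm_kg=eaf_norm_kg, c_oc=c_oc
    )
    by_id = {r.receptor_id: r for r in roster}
    unit_rcr = {
        rid: v for rid, res in unit_results.items()
        if (v := compute_rcr(res, by_id[rid], chem)) is not None
    }
    haf, haf_rid = _argmax_roster_order(unit_rcr, roster)
    if haf is None:
        diagnostics.append(
            f"{chem.substance_id}: all toxicity thresholds missing; "
            "HAF/RAF undefined"
        )
        haf = float("nan")

    if scenario.total_rate == 0.0:
        rcr_map: dict[str, float] = {rid: 0.0 for rid in unit_rcr}
        raf, raf_rid = (0.0, None) if rcr_map or haf == haf else (float("nan"), None)
        if haf != haf:
            raf = float("nan")
    else:
        _, actual_results = run_receptors(chem, env, roster, params, scenario, c_oc)
        rcr_map = {
            rid: v for rid, res in actual_results.items()
            if (v := compute_rcr(res, by_id[rid], chem)) is not None
        }
        raf, raf_rid = _argmax_roster_order(rcr_map, roster)
        if raf is None:
            raf = float("nan")

    return RiskMetrics(
        substance_id=chem.substance_id,
        scope_key=scenario.scope_key,
        eaf=eaf, eaf_receptor=eaf_rid,
        haf=haf, haf_receptor=haf_rid,
        rcr=rcr_map, raf=raf, most_sensitive_receptor=raf_rid,
        moe_unit=moe_unit, moe_actual=tuple(scenario.moe_fractions),
        actual_rate_kg_h=scenario.total_rate,
        p_ov_reaction_days=unit_fate.p_ov_reaction_days,
        diagnostics=diagnostics,
    )
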