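"""End-to-end composition: properties + releases -> metrics, ranks, totals.

These functions are the library's high-level surface; the CLI, the examples
and the acceptance machinery are thin layers over them.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .bioacc import BioaccParams, Receptor, load_roster
from .environment import EvaluativeEnvironment, load_environment
from .inventory import (
    HOURS_PER_YEAR,
    EmissionScenario,
    ReleaseRecord,
    build_scenarios,
    records_to_frame,
)
from .metrics import RiskMetrics, compute_haf_raf, compute_rcr, run_receptors
from .properties import ChemicalRecord, PropertyDatabase, fill_missing_toxicity
from .ranking import aggregate_total_risk, rank_substances, trend_slope

logger = logging.getLogger(__name__)

__all__ = [
    "substance_metrics", "metrics_frame", "ranking_tables",
    "total_risk_by_group", "timeseries_totals", "risk_per_tonne",
    "write_csv_with_metadata",
]


def _prepare(env, roster, params):
    if env is None:
        env = load_environment()
    if roster is None or params is None:
        r, p = load_roster()
        roster = roster or r
        params = params or p
    return env, roster, params


def substance_metrics(
    db: PropertyDatabase,
    scenarios: Sequence[EmissionScenario],
    env: EvaluativeEnvironment | None = None,
    roster: list[Receptor] | None = None,
    params: BioaccParams | None = None,
    *,
    tox_policy: str = "skip-receptor",
    moe_convention: str = "actual",
    eaf_norm_kg: float = 1.0,
    c_oc: float = 0.35,
) -> list[RiskMetrics]:
    """Compute the four screening metrics for every scenario.

    Scenarios whose substance is absent from the property database are
    dropped with a logged count (release inventories routinely list more
    substances than any property database covers).
    """
    env, roster, params = _prepare(env, roster, params)
    out: list[RiskMetrics] = []
    dropped = 0
    for sc in scenarios:
        if sc.substance_id not in db:
            dropped += 1
            continue
        chem = fill_missing_toxicity(db[sc.substance_id], tox_policy)
        out.append(
            compute_haf_raf(
                chem, env, roster, params, sc,
                moe_convention=moe_convention, eaf_norm_kg=eaf_norm_kg, c_oc=c_oc,
            )
        )
    if dropped:
        logger.info("dropped %d scenario(s) for substances without property records", dropped)
    return out


def metrics_frame(metrics: Iterable[RiskMetrics]) -> pd.DataFrame:
    """Tabulate RiskMetrics, one row per substance x scenario."""
    rows = []
    for m in metrics:
        sk = m.scope_key
        rows.append({
            "substance_id": m.substance_id,
            "year": sk.year if sk else None,
            "region": sk.region if sk else None,
            "sector": sk.sector if sk else None,
            "rate_kg_h": m.actual_rate_kg_h,
            "quantity_tonnes": m.actual_rate_kg_h * HOURS_PER_YEAR / 1000.0,
            "moe_air": m.moe_actual[0],
            "moe_water": m.moe_actual[1],
            "moe_soil": m.moe_actual[2],
            "p_ov_reaction_days": m.p_ov_reaction_days,
            "eaf": m.eaf,
            "eaf_receptor": m.eaf_receptor,
            "haf": m.haf,
            "haf_receptor": m.haf_receptor,
            "raf": m.raf,
            "most_sensitive_receptor": m.most_sensitive_receptor,
            "sum_rcr": sum(m.rcr.values()),
        })
    return pd.DataFrame(rows)


def ranking_tables(metrics_df: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """The four ranked substance tables (quantity, EAF, HAF, RAF)."""
    return {ordering: rank_substances(metrics_df, ordering)
            for ordering in ("quantity", "eaf", "haf", "raf")}


def total_risk_by_group(
    db: PropertyDatabase,
    records: Sequence[ReleaseRecord],
    group_by: str,
    year: int | None = None,
    env: EvaluativeEnvironment | None = None,
    roster: list[Receptor] | None = None,
    params: BioaccParams | None = None,
    *,
    tox_policy: str = "skip-receptor",
    c_oc: float = 0.35,
) -> pd.DataFrame:
    """"Total risk" aggregation over provinces/territories, sectors or years.

    Each group gets its own emission scenarios (group rates and group MOE);
    its total risk is the sum of all per-receptor RCRs of all substances.
    """
    if group_by not in ("region", "sector", "year"):
        raise ValueError(f"group_by must be region/sector/year, got {group_by!r}")
    env, roster, params = _prepare(env, roster, params)
    if year is not None:
        records = [r for r in records if r.year == year]
    scope = ("year",) if group_by == "year" else ("year", group_by)
    scenarios = build_scenarios(records, scope)
    rcr_totals: dict = {}
    for sc in scenarios:
        if sc.substance_id not in db:
            continue
        chem = fill_missing_toxicity(db[sc.substance_id], tox_policy)
        m = compute_haf_raf(chem, env, roster, params, sc, c_oc=c_oc)
        key = getattr(sc.scope_key, group_by)
        rcr_totals[key] = rcr_totals.get(key, 0.0) + sum(m.rcr.values())
    df = records_to_frame(records)
    qty = df.groupby(group_by)["quantity"].sum().to_dict() if not df.empty else {}
    return aggregate_total_risk(rcr_totals, qty)


def timeseries_totals(
    db: PropertyDatabase,
    records: Sequence[ReleaseRecord],
    env: EvaluativeEnvironment | None = None,
    roster: list[Receptor] | None = None,
    params: BioaccParams | None = None,
    *,
    tox_policy: str = "skip-receptor",
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-year total quantity and total risk, with OLS trend slopes."""
    agg = total_risk_by_group(db, records, "year", env=env, roster=roster,
                              params=params, tox_policy=tox_policy)
    qty_series = dict(zip(agg["group"].astype(int), agg["total_quantity_tonnes"]))
    rcr_series = dict(zip(agg["group"].astype(int), agg["total_rcr"]))
    q_slope, q_icpt = trend_slope(qty_series)
    r_slope, r_icpt = trend_slope(rcr_series)
    slopes = {
        "quantity_slope_tonnes_per_year": q_slope,
        "quantity_intercept": q_icpt,
        "rcr_slope_per_year": r_slope,
        "rcr_intercept": r_icpt,
    }
    return agg.rename(columns={"group": "year"}), slopes


def risk_per_tonne(
    chem: ChemicalRecord,
    compartment: str,
    env: EvaluativeEnvironment | None = None,
    roster: list[Receptor] | None = None,
    params: BioaccParams | None = None,
    *,
    tox_policy: str = "skip-receptor",
) -> float:
    """Summed receptor RCR for 1 tonne/yr emitted wholly to one compartment.

    Decomposes trend differences by mode of entry: the same tonnage emitted
    to air vs. soil can carry very different risk.
    """
    env, roster, params = _prepare(env, roster, params)
    moe = {"air": (1.0, 0.0, 0.0), "water": (0.0, 1.0, 0.0), "soil": (0.0, 0.0, 1.0)}[compartment]
    rate = 1.0 * 1000.0 / HOURS_PER_YEAR
    chem = fill_missing_toxicity(chem, tox_policy)
    scenario = EmissionScenario(chem.substance_id, rate, moe)
    _, results = run_receptors(chem, env, roster, params, scenario)
    by_id = {r.receptor_id: r for r in roster}
    total = 0.0
    for rid, res in results.items():
        v = compute_rcr(res, by_id[rid], chem)
        if v is not None:
            total += v
    return total


def write_csv_with_metadata(df: pd.DataFrame, path, metadata: Mapping[str, object] | None = None) -> None:
    """Write a CSV with a ``#``-comment metadata header block."""
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}: {v}\n")
        caveat = df.attrs.get("caveat")
        if caveat:
            fh.write(f"# caveat: {caveat}\n")
        df.to_csv(fh, index=False)
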