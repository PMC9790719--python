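"""Ranking tables, total-risk aggregation and time-trend slopes.

Substances can be ranked by release quantity, EAF, HAF or RAF (rank 1 =
largest).  "Total risk" for a region/sector/year is the plain sum of all
per-receptor RCRs of all substances in the group — strictly valid only for
baseline-toxicity modes of action, which is why aggregate outputs carry an
explicit additivity-caveat flag.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "RANK_ORDERINGS", "RankingError", "ADDITIVITY_CAVEAT",
    "rank_substances", "aggregate_total_risk", "trend_slope",
]

RANK_ORDERINGS = ("quantity", "eaf", "haf", "raf")

ADDITIVITY_CAVEAT = (
    "total_rcr assumes additivity of risk ratios, strictly valid only for "
    "baseline (narcosis) modes of toxic action"
)


class RankingError(ValueError):
    """Invalid ranking/aggregation input."""


_METRIC_COLUMN = {
    "quantity": "quantity_tonnes",
    "eaf": "eaf",
    "haf": "haf",
    "raf": "raf",
}
_RECEPTOR_COLUMN = {
    "eaf": "eaf_receptor",
    "haf": "haf_receptor",
    "raf": "most_sensitive_receptor",
}


def rank_substances(metrics: pd.DataFrame, ordering: str) -> pd.DataFrame:
    """Rank one-row-per-substance metrics under the given ordering.

    Ranks are competition style: ties share the smallest applicable rank,
    with a deterministic secondary sort by substance_id.  NaN metric values
    sort last.
    """
    if ordering not in RANK_ORDERINGS:
        raise RankingError(f"unknown ordering {ordering!r}; expected {RANK_ORDERINGS}")
    col = _METRIC_COLUMN[ordering]
    if col not in metrics.columns:
        raise RankingError(f"metrics table lacks column {col!r}")
    if metrics["substance_id"].duplicated().any():
        dups = metrics.loc[metrics["substance_id"].duplicated(), "substance_id"]
        raise RankingError(f"duplicate substance(s) in input: {sorted(set(dups))}")
    out = metrics.copy()
    out["rank"] = out[col].rank(method="min", ascending=False, na_option="bottom")
    out["rank"] = out["rank"].astype(int)
    out = out.sort_values(["rank", "substance_id"], kind="mergesort").reset_index(drop=True)
    cols = ["rank", "substance_id", col]
    rcol = _RECEPTOR_COLUMN.get(ordering)
    if rcol and rcol in out.columns:
        cols.append(rcol)
    return out[cols].rename(columns={col: "metric"})


def aggregate_total_risk(
    rcr_totals: Mapping[str, float],
    quantities: Mapping[str, float],
) -> pd.DataFrame:
    """Combine per-group summed RCRs and per-group quantities.

    ``rcr_totals`` maps group key -> sum over substances and receptors of
    RCR computed from that group's own emission scenarios; ``quantities``
    maps group key -> total tonnes.  Returns a table with risk and quantity
    shares; the frame's ``attrs['caveat']`` carries the additivity caveat.
    """
    groups = sorted(set(rcr_totals) | set(quantities), key=str)
    total_rcr = sum(rcr_totals.values())
    total_qty = sum(quantities.values())
    df = pd.DataFrame({
        "group": groups,
        "total_quantity_tonnes": [quantities.get(g, 0.0) for g in groups],
        "total_rcr": [rcr_totals.get(g, 0.0) for g in groups],
    })
    df["share_rcr"] = df["total_rcr"] / total_rcr if total_rcr > 0 else 0.0
    df["share_quantity"] = (
        df["total_quantity_tonnes"] / total_qty if total_qty > 0 else 0.0
    )
    df.attrs["caveat"] = ADDITIVITY_CAVEAT
    return df


def trend_slope(series: Mapping[int, float]) -> tuple[float, float]:
    """Ordinary least-squares slope and intercept of a year -> value series.

    The slope carries the units of the series per year.
    """
    if len(series) < 2:
        raise RankingError("trend requires at least 2 points")
    years = np.array(sorted(series), dtype=float)
    values = np.array([series[int(y)] for y in years], dtype=float)
    slope, intercept = np.polyfit(years, values, 1)
    return float(slope), float(intercept)
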