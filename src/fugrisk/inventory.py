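"""Release-inventory parsing and emission-scenario construction.

Reads PRTR-style disaggregated release tables (facility, region, NAICS-like
sector, year, substance, receiving compartment, annual tonnes) and converts
them into steady-state regional emission scenarios: a rate in kg/h and a
mode-of-entry (MOE) split over air, water and soil.  Annual totals are
scaled with 8760 h/yr; "land" releases map to the model's surface-soil
compartment.  Disposal categories (landfill, underground injection, ...)
are out of scope and rejected by the reader.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

__all__ = [
    "ReleaseRecord",
    "EmissionScenario",
    "ScopeKey",
    "InventoryError",
    "read_release_table",
    "write_release_table",
    "build_scenarios",
    "RELEASE_COLUMNS",
    "HOURS_PER_YEAR",
]

HOURS_PER_YEAR = 8760.0

#: Receiving compartments accepted in release records ("land" is a synonym
#: mapped to soil when scenarios are built).
RELEASE_COMPARTMENTS = ("air", "water", "land")

#: MOE compartments of the fate model, in fixed order.
MOE_COMPARTMENTS = ("air", "water", "soil")

RELEASE_COLUMNS = (
    "facility_id",
    "region",
    "sector",
    "year",
    "substance_id",
    "compartment",
    "quantity",
)


class InventoryError(ValueError):
    """Malformed release-inventory input."""


@dataclass(frozen=True)
class ReleaseRecord:
    """One facility's annual release of one substance to one compartment."""

    facility_id: str
    region: str
    sector: str
    year: int
    substance_id: str
    compartment: str  # air | water | land
    quantity: float  # tonnes/year

    def __post_init__(self):
        if self.compartment not in RELEASE_COMPARTMENTS:
            raise InventoryError(
                f"unknown compartment {self.compartment!r}; releases must go to "
                f"{RELEASE_COMPARTMENTS} (disposal streams are out of scope)"
            )
        if not self.quantity >= 0:
            raise InventoryError(f"quantity must be >= 0, got {self.quantity}")


class ScopeKey(NamedTuple):
    """Grouping key an emission scenario aggregates over."""

    year: int
    region: str | None = None
    sector: str | None = None


@dataclass(frozen=True)
class EmissionScenario:
    """Steady-state emission rate and mode of entry for one substance."""

    substance_id: str
    total_rate: float  # kg/h
    moe_fractions: tuple[float, float, float]  # (air, water, soil), sums to 1
    scope_key: ScopeKey | None = None

    def __post_init__(self):
        if not self.total_rate >= 0:
            raise InventoryError(f"total_rate must be >= 0, got {self.total_rate}")
        s = sum(self.moe_fractions)
        if self.total_rate > 0 and abs(s - 1.0) > 1e-12:
            raise InventoryError(f"moe_fractions must sum to 1, got {s!r}")
        if any(f < 0 or f > 1 for f in self.moe_fractions):
            raise InventoryError("moe_fractions must lie in [0, 1]")


def read_release_table(
    path,
    dialect: Mapping[str, str] | None = None,
    *,
    year_span: tuple[int, int] | None = None,
) -> list[ReleaseRecord]:
    """Read a delimited release table into validated records.

    Substances absent from any property database are retained here;
    filtering happens at join time with diagnostics.
    """
    dialect = dict(dialect or {})
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    cols = {c: dialect.get(c, c) for c in RELEASE_COLUMNS}
    missing = [a for a in cols.values() if a not in df.columns]
    if missing:
        raise InventoryError(f"missing required column(s): {missing}")
    records = []
    for idx, row in df.iterrows():
        try:
            qty = float(row[cols["quantity"]])
        except (TypeError, ValueError):
            raise InventoryError(
                f"malformed quantity {row[cols['quantity']]!r} in row {idx}"
            ) from None
        year = int(row[cols["year"]])
        if year_span is not None and not year_span[0] <= year <= year_span[1]:
            raise InventoryError(f"year {year} outside configured span {year_span} (row {idx})")
        records.append(
            ReleaseRecord(
                facility_id=str(row[cols["facility_id"]]),
                region=str(row[cols["region"]]),
                sector=str(row[cols["sector"]]),
                year=year,
                substance_id=str(row[cols["substance_id"]]),
                compartment=str(row[cols["compartment"]]).strip().lower(),
                quantity=qty,
            )
        )
    return records


def write_release_table(records: Iterable[ReleaseRecord], path,
                        dialect: Mapping[str, str] | None = None) -> None:
    dialect = dict(dialect or {})
    df = records_to_frame(records)
    # repr of floats round-trips bit-identically through the reader
    df["quantity"] = df["quantity"].map(repr)
    df.columns = [dialect.get(c, c) for c in df.columns]
    df.to_csv(path, index=False)


def records_to_frame(records: Iterable[ReleaseRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {c: getattr(r, c) for c in RELEASE_COLUMNS}
            for r in records
        ],
        columns=list(RELEASE_COLUMNS),
    )


#: Uniform placeholder MOE used for zero-total groups.
UNIFORM_MOE = (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)

_COMPARTMENT_TO_MOE = {"air": "air", "water": "water", "land": "soil"}


def build_scenarios(
    records: Sequence[ReleaseRecord],
    scope: Sequence[str] = ("year",),
    *,
    hours_per_year: float = HOURS_PER_YEAR,
    rate_scaling: float = 1.0,
) -> list[EmissionScenario]:
    """Aggregate release records into per-group emission scenarios.

    ``scope`` names the grouping keys; ``year`` is mandatory, ``region`` and
    ``sector`` optional.  Per group and substance the rate is
    ``sum(quantity) * 1000 / hours_per_year`` kg/h and the MOE fractions are
    the compartment subtotals over the total (land mapped to soil).
    ``rate_scaling`` is an optional sensitivity factor (default 1: the summed
    national rate is applied to the evaluative region unscaled).
    """
    scope = tuple(scope)
    if "year" not in scope:
        raise InventoryError("scenario scope must include 'year'")
    extra = set(scope) - {"year", "region", "sector"}
    if extra:
        raise InventoryError(f"unknown scope key(s): {sorted(extra)}")
    df = records_to_frame(records)
    if df.empty:
        return []
    df["moe_compartment"] = df["compartment"].map(_COMPARTMENT_TO_MOE)
    keys = ["substance_id", "year"]
    if "region" in scope:
        keys.append("region")
    if "sector" in scope:
        keys.append("sector")
    scenarios = []
    grouped = df.groupby(keys, sort=True)
    for key, grp in grouped:
        key = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        total_tonnes = grp["quantity"].sum()
        rate = total_tonnes * 1000.0 / hours_per_year * rate_scaling
        if total_tonnes > 0:
            by_comp = grp.groupby("moe_compartment")["quantity"].sum()
            moe = tuple(
                min(1.0, max(0.0, float(by_comp.get(c, 0.0)) / total_tonnes))
                for c in MOE_COMPARTMENTS
            )
        else:
            moe = UNIFORM_MOE
        scenarios.append(
            EmissionScenario(
                substance_id=str(key["substance_id"]),
                total_rate=float(rate),
                moe_fractions=moe,
                scope_key=ScopeKey(
                    year=int(key["year"]),
                    region=key.get("region"),
                    sector=key.get("sector"),
                ),
            )
        )
    return scenarios
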