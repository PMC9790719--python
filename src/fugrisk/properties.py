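"""Chemical property database.

One :class:`ChemicalRecord` holds everything the fate, bioaccumulation and
risk stages need for a single organic substance: molar mass, the two
partition coefficients (log KOW, log KAW), first-order degradation half-lives
per environmental medium, whole-body biotransformation half-lives at two
reference body masses (0.01 kg for water-respiring ectotherms, 70 kg for
birds and mammals), aquatic toxicity thresholds per taxon (mmol/L) and a
generic intake-rate threshold for air-breathing receptors (mg/kg/day).

Group listings (e.g. a dioxin/furan total expressed as TCDD toxic
equivalents) are modelled as a single pseudo-chemical carrying the
properties of a designated representative congener, flagged ``is_group``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

import pandas as pd

__all__ = [
    "ChemicalRecord",
    "PropertyDatabase",
    "PropertyError",
    "DerivedCoefficients",
    "read_property_table",
    "write_property_table",
    "derived_partition_coefficients",
    "fill_missing_toxicity",
    "PROPERTY_COLUMNS",
]

#: Validity windows for the partition coefficients (span of the substances
#: the database is designed to describe; configurable in the reader).
LOG_KOW_WINDOW = (-3.8, 12.1)
LOG_KAW_WINDOW = (-14.3, 2.5)

#: Canonical column names of the delimited property table.
PROPERTY_COLUMNS = (
    "substance_id",
    "name",
    "molar_mass",
    "log_kow",
    "log_kaw",
    "hl_air",
    "hl_water",
    "hl_soil",
    "hl_sediment",
    "hl_biotrans_aquatic",
    "hl_biotrans_airbreather",
    "c_tox_autotroph",
    "c_tox_invertebrate",
    "c_tox_fish",
    "ir_threshold",
    "is_group",
)

_NUMERIC_REQUIRED = (
    "molar_mass",
    "log_kow",
    "log_kaw",
    "hl_air",
    "hl_water",
    "hl_soil",
    "hl_sediment",
    "hl_biotrans_aquatic",
    "hl_biotrans_airbreather",
)
_NUMERIC_OPTIONAL = (
    "c_tox_autotroph",
    "c_tox_invertebrate",
    "c_tox_fish",
    "ir_threshold",
)


class PropertyError(ValueError):
    """Malformed or invalid chemical-property input."""


@dataclass
class ChemicalRecord:
    """Physchem, degradation, biotransformation and toxicity parameters."""

    substance_id: str
    name: str
    molar_mass: float  # g/mol
    log_kow: float
    log_kaw: float
    hl_air: float  # h
    hl_water: float  # h
    hl_soil: float  # h
    hl_sediment: float  # h
    hl_biotrans_aquatic: float  # h, referenced to 0.01 kg body mass
    hl_biotrans_airbreather: float  # h, referenced to 70 kg body mass
    c_tox_autotroph: float | None = None  # mmol/L
    c_tox_invertebrate: float | None = None  # mmol/L
    c_tox_fish: float | None = None  # mmol/L
    ir_threshold: float | None = None  # mg/kg/day
    is_group: bool = False

    @property
    def kow(self) -> float:
        return 10.0 ** self.log_kow

    @property
    def kaw(self) -> float:
        return 10.0 ** self.log_kaw

    def validation_errors(
        self,
        kow_window: tuple[float, float] = LOG_KOW_WINDOW,
        kaw_window: tuple[float, float] = LOG_KAW_WINDOW,
    ) -> list[str]:
        """Return human-readable invariant violations (empty when valid)."""
        errs: list[str] = []
        if not (self.molar_mass > 0 and math.isfinite(self.molar_mass)):
            errs.append(f"molar_mass must be positive and finite, got {self.molar_mass}")
        for fld in ("hl_air", "hl_water", "hl_soil", "hl_sediment",
                    "hl_biotrans_aquatic", "hl_biotrans_airbreather"):
            v = getattr(self, fld)
            if not (v > 0 and math.isfinite(v)):
                errs.append(f"{fld} must be positive and finite, got {v}")
        for fld in _NUMERIC_OPTIONAL:
            v = getattr(self, fld)
            if v is not None and not (v > 0 and math.isfinite(v)):
                errs.append(f"{fld} must be positive when present, got {v}")
        if not math.isfinite(self.log_kow) or not kow_window[0] <= self.log_kow <= kow_window[1]:
            errs.append(f"log_kow {self.log_kow} outside validity window {kow_window}")
        if not math.isfinite(self.log_kaw) or not kaw_window[0] <= self.log_kaw <= kaw_window[1]:
            errs.append(f"log_kaw {self.log_kaw} outside validity window {kaw_window}")
        return errs


@dataclass
class PropertyDatabase:
    """Collection of :class:`ChemicalRecord` keyed by ``substance_id``.

    Lookup of a missing id raises ``KeyError``; there is no silent default.
    """

    records: dict[str, ChemicalRecord] = field(default_factory=dict)
    provenance: str = ""
    #: Row-level diagnostics for rows rejected by the reader.
    diagnostics: list[str] = field(default_factory=list)

    def add(self, record: ChemicalRecord) -> None:
        if record.substance_id in self.records:
            raise PropertyError(f"duplicate substance_id {record.substance_id!r}")
        self.records[record.substance_id] = record

    def __getitem__(self, substance_id: str) -> ChemicalRecord:
        try:
            return self.records[substance_id]
        except KeyError:
            raise KeyError(
                f"substance {substance_id!r} not in property database"
            ) from None

    def __contains__(self, substance_id: str) -> bool:
        return substance_id in self.records

    def __iter__(self) -> Iterator[ChemicalRecord]:
        return iter(self.records.values())

    def __len__(self) -> int:
        return len(self.records)

    @property
    def substance_ids(self) -> list[str]:
        return list(self.records)


def _resolve_columns(columns: Iterable[str], dialect: Mapping[str, str] | None) -> dict[str, str]:
    """Map canonical field names to actual file columns."""
    dialect = dict(dialect or {})
    mapping = {}
    cols = set(columns)
    for canonical in PROPERTY_COLUMNS:
        actual = dialect.get(canonical, canonical)
        if actual in cols:
            mapping[canonical] = actual
    required = set(PROPERTY_COLUMNS) - {"name", "is_group", *_NUMERIC_OPTIONAL}
    missing = required - set(mapping)
    if missing:
        raise PropertyError(f"missing required column(s): {sorted(missing)}")
    return mapping


def read_property_table(
    path,
    dialect: Mapping[str, str] | None = None,
    *,
    kow_window: tuple[float, float] = LOG_KOW_WINDOW,
    kaw_window: tuple[float, float] = LOG_KAW_WINDOW,
    provenance: str = "",
) -> PropertyDatabase:
    """Read a delimited chemical-property table into a validated database.

    Rows violating record invariants are rejected and reported in
    ``db.diagnostics``; structural problems (missing column, duplicated id,
    non-numeric value in a numeric field) raise :class:`PropertyError`.
    """
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    mapping = _resolve_columns(df.columns, dialect)
    db = PropertyDatabase(provenance=provenance or str(path))
    ids_seen: set[str] = set()
    for idx, row in df.iterrows():
        sid = str(row[mapping["substance_id"]])
        if sid in ids_seen:
            raise PropertyError(f"duplicate substance_id {sid!r} (row {idx})")
        ids_seen.add(sid)
        kwargs: dict = {"substance_id": sid}
        kwargs["name"] = str(row[mapping["name"]]) if "name" in mapping else sid
        for fld in _NUMERIC_REQUIRED:
            raw = row[mapping[fld]]
            try:
                kwargs[fld] = float(raw)
            except (TypeError, ValueError):
                raise PropertyError(
                    f"non-numeric value {raw!r} for {fld} in row {idx} ({sid})"
                ) from None
        for fld in _NUMERIC_OPTIONAL:
            if fld in mapping:
                raw = row[mapping[fld]]
                if pd.isna(raw):
                    kwargs[fld] = None
                else:
                    try:
                        kwargs[fld] = float(raw)
                    except (TypeError, ValueError):
                        raise PropertyError(
                            f"non-numeric value {raw!r} for {fld} in row {idx} ({sid})"
                        ) from None
        if "is_group" in mapping:
            kwargs["is_group"] = bool(row[mapping["is_group"]]) and str(
                row[mapping["is_group"]]
            ).lower() not in ("false", "0", "no", "nan")
        rec = ChemicalRecord(**kwargs)
        errs = rec.validation_errors(kow_window, kaw_window)
        if errs:
            db.diagnostics.append(f"row {idx} ({sid}) rejected: " + "; ".join(errs))
            ids_seen.discard(sid)
            continue
        db.add(rec)
    return db


def write_property_table(db: PropertyDatabase, path, dialect: Mapping[str, str] | None = None) -> None:
    """Write a property database as delimited text (round-trips exactly)."""
    dialect = dict(dialect or {})
    def fmt(v):
        # repr of Python floats is the shortest round-trip representation,
        # so write-then-read is bit-identical
        if v is None:
            return ""
        if isinstance(v, float):
            return repr(v)
        return v

    rows = []
    for rec in db:
        rows.append({dialect.get(c, c): fmt(getattr(rec, c)) for c in PROPERTY_COLUMNS})
    df = pd.DataFrame(rows, columns=[dialect.get(c, c) for c in PROPERTY_COLUMNS])
    df.to_csv(path, index=False)


@dataclass(frozen=True)
class DerivedCoefficients:
    """Partition coefficients derived from KOW and KAW."""

    log_koa: float
    koa: float
    log_koc: float
    koc: float  # L/kg


def derived_partition_coefficients(
    chem: ChemicalRecord, c_oc: float = 0.35
) -> DerivedCoefficients:
    """Octanol-air and organic-carbon partition coefficients.

    KOA = KOW / KAW (thermodynamic triangle); KOC = c_oc * KOW with the
    proportionality constant on an L/kg-organic-carbon basis.
    """
    if not (math.isfinite(chem.log_kow) and math.isfinite(chem.log_kaw)):
        raise PropertyError("log_kow and log_kaw must be finite")
    log_koa = chem.log_kow - chem.log_kaw
    log_koc = math.log10(c_oc) + chem.log_kow
    return DerivedCoefficients(
        log_koa=log_koa, koa=10.0 ** log_koa, log_koc=log_koc, koc=10.0 ** log_koc
    )


#: Baseline-narcosis QSAR coefficients: log(1/C_T[mol/L]) = a*log KOW + b.
NARCOSIS_A = 0.85
NARCOSIS_B = 1.39

TOX_POLICIES = ("skip-receptor", "baseline-narcosis")


def narcosis_threshold_mmol_l(
    log_kow: float,
    a: float = NARCOSIS_A,
    b: float = NARCOSIS_B,
    ceiling_mmol_l: float | None = None,
) -> float:
    """Baseline-narcosis aquatic effect threshold, mmol/L."""
    ct_mol_l = 10.0 ** (-(a * log_kow + b))
    ct = ct_mol_l * 1000.0
    if ceiling_mmol_l is not None:
        ct = min(ct, ceiling_mmol_l)
    return ct


def fill_missing_toxicity(
    chem: ChemicalRecord,
    policy: str = "skip-receptor",
    *,
    a: float = NARCOSIS_A,
    b: float = NARCOSIS_B,
    ceiling_mmol_l: float | None = None,
) -> ChemicalRecord:
    """Apply the missing-threshold policy to one record.

    ``"skip-receptor"`` leaves missing thresholds missing (the affected
    receptor's risk ratio is later excluded from max/sum); this is the
    conservative default, which never invents potency.  ``"baseline-narcosis"``
    fills missing aquatic thresholds from the one-parameter narcosis
    relation on KOW, optionally capped at a solubility-driven ceiling.
    """
    if policy not in TOX_POLICIES:
        raise PropertyError(f"unknown toxicity policy {policy!r}; expected one of {TOX_POLICIES}")
    if policy == "skip-receptor":
        return chem
    fill = narcosis_threshold_mmol_l(chem.log_kow, a, b, ceiling_mmol_l)
    updates = {
        fld: fill
        for fld in ("c_tox_autotroph", "c_tox_invertebrate", "c_tox_fish")
        if getattr(chem, fld) is None
    }
    return replace(chem, **updates) if updates else chem
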