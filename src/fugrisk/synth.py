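"""Synthetic chemical-property databases and PRTR-like release inventories.

The generator emulates the structure of a national pollutant release and
transfer register extract (facility, province/territory, 3-digit NAICS-like
sector, year, substance, receiving compartment, annual tonnes) and a
matching organic-chemical property database.  Sampling ranges default to
the spans of the study population the package is designed for: log KOW in
[-3.8, 12.1], log KAW in [-14.3, 2.5], degradation half-lives log-uniform
within their per-medium ranges, aquatic toxicity coupled to hydrophobicity
through the baseline-narcosis relation plus lognormal noise, and lognormal
annual tonnages.

Two deterministic archetype fixtures anchor the qualitative contrasts the
pipeline must be able to reproduce:

* ``solvent-like`` — very high release volume, short half-lives, low KOW:
  high quantity rank, low exposure/hazard potential (an ethanol analogue);
* ``dioxin-like`` — trace volume, half-lives and biotransformation
  half-lives at the persistent extreme of the configured ranges, high KOW,
  very low toxicity thresholds (a TCDD-equivalents group analogue).

An optional mode-of-entry drift shifts a chosen substance's releases from
air toward land across years while its tonnage grows, emulating inventories
whose total quantity rises while total risk stays flat.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .inventory import ReleaseRecord
from .properties import ChemicalRecord, PropertyDatabase, narcosis_threshold_mmol_l

__all__ = [
    "GeneratorConfig", "MOEDrift", "DEFAULT_BOUNDS",
    "generate_property_db", "generate_release_inventory",
    "solvent_like_record", "dioxin_like_record", "semivolatile_like_record",
    "median_like_record", "moe_drift_fixture",
]

#: Default per-parameter sampling bounds (property-table units).
DEFAULT_BOUNDS: Mapping[str, tuple[float, float]] = {
    "molar_mass": (26.0, 959.2),
    "log_kow": (-3.8, 12.1),
    "log_kaw": (-14.3, 2.5),
    "hl_air": (0.19, 1.0e6),
    "hl_water": (55.0, 7.2e4),
    "hl_soil": (110.0, 1.4e5),
    "hl_sediment": (494.0, 6.5e5),
    "hl_biotrans_aquatic": (0.16, 6.6e3),
    "hl_biotrans_airbreather": (0.05, 8.5e5),
    "c_tox_autotroph": (1.2e-6, 230.0),
    "c_tox_invertebrate": (1.4e-6, 1270.0),
    "c_tox_fish": (3.1e-8, 997.0),
}


@dataclass(frozen=True)
class MOEDrift:
    """Year-over-year shift of one substance's mode of entry air -> land."""

    substance_id: str
    air_start: float = 0.9
    air_end: float = 0.1
    water_fraction: float = 0.02  # constant small share to water
    tonnage_growth: float = 0.10  # fractional tonnage growth per year
    base_tonnes: float = 1000.0  # first-year tonnage of the drifting substance


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 1
    n_substances: int = 20
    n_facilities: int = 40
    regions: tuple[str, ...] = ("ON", "QC", "BC", "AB", "SK", "MB")
    sectors: tuple[str, ...] = ("211", "312", "325", "322", "324", "113")
    years: tuple[int, ...] = tuple(range(2010, 2020))
    bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    # lognormal annual tonnage (per substance-year): ln-space mean and sd
    quantity_ln_mu: float = 4.0  # ~55 tonnes median
    quantity_ln_sigma: float = 2.5
    # archetype tonnage scales, tonnes/yr
    solvent_tonnes: float = 2.0e4
    dioxin_tonnes: float = 1.0e-4
    # Dirichlet concentration for the (air, water, land) MOE split
    moe_alpha: tuple[float, float, float] = (1.2, 0.5, 0.5)
    # lognormal (log10 sd) noise on the narcosis-coupled toxicity thresholds
    narcosis_log10_sd: float = 0.5
    # probability a taxon's threshold is missing (partial coverage)
    p_missing: Mapping[str, float] = field(default_factory=lambda: {
        "c_tox_autotroph": 0.43, "c_tox_invertebrate": 0.15, "c_tox_fish": 0.07,
    })
    ir_threshold: float = 0.15  # mg/kg/day, generic for birds/mammals/human
    include_archetypes: bool = True
    #: deterministic records appended verbatim to the generated database
    extra_records: tuple[ChemicalRecord, ...] = ()
    moe_drift: MOEDrift | None = None


def solvent_like_record() -> ChemicalRecord:
    """High-volume, rapidly degraded, hydrophilic archetype (ethanol-like)."""
    return ChemicalRecord(
        substance_id="solvent-like", name="solvent-like archetype",
        molar_mass=46.1, log_kow=-0.31, log_kaw=-3.6,
        hl_air=50.0, hl_water=55.0, hl_soil=110.0, hl_sediment=494.0,
        hl_biotrans_aquatic=0.5, hl_biotrans_airbreather=0.5,
        c_tox_autotroph=230.0, c_tox_invertebrate=300.0, c_tox_fish=300.0,
        ir_threshold=0.15,
    )


def dioxin_like_record() -> ChemicalRecord:
    """Trace-volume, persistent, bioaccumulative, potent archetype
    (dioxin/furan TEQ group analogue carrying representative-congener
    properties at the persistent extreme of the default bounds)."""
    return ChemicalRecord(
        substance_id="dioxin-like", name="dioxin-like archetype (group TEQ)",
        molar_mass=322.0, log_kow=6.8, log_kaw=-2.9,
        hl_air=1.0e6, hl_water=7.2e4, hl_soil=1.4e5, hl_sediment=6.5e5,
        hl_biotrans_aquatic=6.6e3, hl_biotrans_airbreather=8.5e5,
        c_tox_autotroph=1.2e-6, c_tox_invertebrate=1.4e-6, c_tox_fish=3.1e-8,
        ir_threshold=0.15, is_group=True,
    )


def median_like_record() -> ChemicalRecord:
    """A typical organic substance: every parameter at the median of the
    default bounds' source population (useful as a neutral test chemical)."""
    return ChemicalRecord(
        substance_id="median-like", name="median-parameter substance",
        molar_mass=134.8, log_kow=2.4, log_kaw=-3.2,
        hl_air=36.6, hl_water=480.0, hl_soil=970.0, hl_sediment=4.4e3,
        hl_biotrans_aquatic=8.5, hl_biotrans_airbreather=4.8,
        c_tox_autotroph=0.11, c_tox_invertebrate=0.12, c_tox_fish=0.17,
        ir_threshold=0.15,
    )


def semivolatile_like_record() -> ChemicalRecord:
    """Semivolatile, foliage-accumulating archetype: high KOW, very low KAW
    (huge KOA), so air releases load foliage and its grazers while soil
    releases stay sorbed with little plant uptake — a strong air-pathway
    asymmetry in risk per tonne, which drives the mode-of-entry trend
    fixture."""
    return ChemicalRecord(
        substance_id="semivolatile-like", name="semivolatile foliage-binding archetype",
        molar_mass=150.0, log_kow=5.0, log_kaw=-5.0,
        hl_air=500.0, hl_water=1000.0, hl_soil=150.0, hl_sediment=1000.0,
        hl_biotrans_aquatic=10.0, hl_biotrans_airbreather=50.0,
        c_tox_autotroph=0.1, c_tox_invertebrate=0.1, c_tox_fish=0.1,
        ir_threshold=0.15,
    )


def moe_drift_fixture(seed: int = 1):
    """Inventory pair for the mode-of-entry trend experiment.

    A semivolatile foliage-binding substance grows in tonnage while its
    releases drift from air toward land; a high-volume solvent-like
    substance provides a constant background.  Returns
    ``(config, db, drift_records, counterfactual_records)`` where the
    counterfactual keeps the identical tonnages but freezes the mode of
    entry at its first-year split.
    """
    drift = MOEDrift(substance_id="semivolatile-like", base_tonnes=1000.0)
    cfg = GeneratorConfig(
        seed=seed, n_substances=0, include_archetypes=False,
        extra_records=(solvent_like_record(), semivolatile_like_record()),
        solvent_tonnes=5000.0, moe_drift=drift,
    )
    db = generate_property_db(cfg)
    drift_records = generate_release_inventory(cfg, db)
    counter_records = generate_release_inventory(cfg, db, counterfactual_no_drift=True)
    return cfg, db, drift_records, counter_records


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def generate_property_db(config: GeneratorConfig) -> PropertyDatabase:
    """Sample a property database; same seed -> identical database."""
    rng = np.random.default_rng(config.seed)
    b = config.bounds
    db = PropertyDatabase(provenance=f"synthetic (seed={config.seed})")
    n_random = config.n_substances - (2 if config.include_archetypes else 0)
    if n_random < 0:
        raise ValueError("n_substances must be >= 2 when archetypes are included")
    for i in range(n_random):
        log_kow = float(rng.uniform(*b["log_kow"]))
        log_kaw = float(rng.uniform(*b["log_kaw"]))
        tox: dict[str, float | None] = {}
        for fld in ("c_tox_autotroph", "c_tox_invertebrate", "c_tox_fish"):
            base = narcosis_threshold_mmol_l(log_kow)
            noisy = base * 10.0 ** rng.normal(0.0, config.narcosis_log10_sd)
            value = float(np.clip(noisy, *b[fld]))
            missing = rng.random() < config.p_missing.get(fld, 0.0)
            tox[fld] = None if missing else value
        db.add(ChemicalRecord(
            substance_id=f"SYN-{i:04d}", name=f"synthetic substance {i}",
            molar_mass=float(rng.uniform(*b["molar_mass"])),
            log_kow=log_kow, log_kaw=log_kaw,
            hl_air=_log_uniform(rng, *b["hl_air"]),
            hl_water=_log_uniform(rng, *b["hl_water"]),
            hl_soil=_log_uniform(rng, *b["hl_soil"]),
            hl_sediment=_log_uniform(rng, *b["hl_sediment"]),
            hl_biotrans_aquatic=_log_uniform(rng, *b["hl_biotrans_aquatic"]),
            hl_biotrans_airbreather=_log_uniform(rng, *b["hl_biotrans_airbreather"]),
            ir_threshold=config.ir_threshold,
            **tox,
        ))
    if config.include_archetypes:
        db.add(solvent_like_record())
        db.add(dioxin_like_record())
    for rec in config.extra_records:
        db.add(rec)
    return db


def generate_release_inventory(
    config: GeneratorConfig,
    db: PropertyDatabase,
    *,
    counterfactual_no_drift: bool = False,
) -> list[ReleaseRecord]:
    """Sample a release inventory for every substance in ``db``.

    Facilities are assigned to regions and sectors; each substance-year
    total is drawn lognormally (archetype-dependent scale) and split over
    compartments by a Dirichlet MOE draw fixed per substance.  With
    ``moe_drift`` configured, the drifting substance's air share declines
    linearly across years while its tonnage grows;
    ``counterfactual_no_drift`` keeps those tonnages but freezes the MOE at
    its first-year value (for like-for-like trend comparisons).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    regions = np.array(config.regions)
    sectors = np.array(config.sectors)
    fac_region = regions[rng.integers(0, len(regions), config.n_facilities)]
    fac_sector = sectors[rng.integers(0, len(sectors), config.n_facilities)]
    years = sorted(config.years)
    records: list[ReleaseRecord] = []
    drift = config.moe_drift
    for sid in sorted(db.substance_ids):
        if drift is not None and sid == drift.substance_id:
            base_tonnes = drift.base_tonnes
        elif sid == "solvent-like":
            base_tonnes = config.solvent_tonnes
        elif sid == "dioxin-like":
            base_tonnes = config.dioxin_tonnes
        else:
            base_tonnes = float(np.exp(rng.normal(config.quantity_ln_mu,
                                                  config.quantity_ln_sigma)))
        moe = rng.dirichlet(config.moe_alpha)  # (air, water, land)
        n_fac = int(rng.integers(1, 4))
        fac_ids = rng.integers(0, config.n_facilities, n_fac)
        weights = rng.dirichlet(np.ones(n_fac))
        for yi, year in enumerate(years):
            tonnes = base_tonnes * float(rng.lognormal(0.0, 0.1))
            moe_y = moe
            if drift is not None and sid == drift.substance_id:
                tonnes = base_tonnes * (1.0 + drift.tonnage_growth) ** yi
                frac = yi / max(len(years) - 1, 1)
                air = (drift.air_start if counterfactual_no_drift
                       else drift.air_start + (drift.air_end - drift.air_start) * frac)
                moe_y = np.array([air, drift.water_fraction,
                                  1.0 - air - drift.water_fraction])
            for f_idx, w in zip(fac_ids, weights):
                for comp, frac_c in zip(("air", "water", "land"), moe_y):
                    qty = tonnes * float(w) * float(frac_c)
                    if qty <= 0:
                        continue
                    records.append(ReleaseRecord(
                        facility_id=f"FAC-{f_idx:04d}",
                        region=str(fac_region[f_idx]),
                        sector=str(fac_sector[f_idx]),
                        year=int(year),
                        substance_id=sid,
                        compartment=comp,
                        quantity=qty,
                    ))
    return records
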