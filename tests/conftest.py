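"""Shared fixtures: default environment/roster, random chemical factory."""

from __future__ import annotations

import numpy as np
import pytest

from fugrisk.bioacc import load_roster
from fugrisk.environment import load_environment
from fugrisk.inventory import EmissionScenario
from fugrisk.properties import ChemicalRecord
from fugrisk.synth import DEFAULT_BOUNDS, GeneratorConfig, generate_property_db


@pytest.fixture(scope="session")
def env():
    return load_environment()


@pytest.fixture(scope="session")
def roster_params():
    return load_roster()


@pytest.fixture(scope="session")
def roster(roster_params):
    return roster_params[0]


@pytest.fixture(scope="session")
def bioacc_params(roster_params):
    return roster_params[1]


@pytest.fixture(scope="session")
def default_db():
    return generate_property_db(GeneratorConfig())


def random_chemical(rng: np.random.Generator, substance_id: str = "RND") -> ChemicalRecord:
    """Draw one chemical uniformly (log-uniform half-lives) from the
    default property bounds."""
    b = DEFAULT_BOUNDS

    def logu(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    return ChemicalRecord(
        substance_id=substance_id, name=substance_id,
        molar_mass=float(rng.uniform(*b["molar_mass"])),
        log_kow=float(rng.uniform(*b["log_kow"])),
        log_kaw=float(rng.uniform(*b["log_kaw"])),
        hl_air=logu(*b["hl_air"]),
        hl_water=logu(*b["hl_water"]),
        hl_soil=logu(*b["hl_soil"]),
        hl_sediment=logu(*b["hl_sediment"]),
        hl_biotrans_aquatic=logu(*b["hl_biotrans_aquatic"]),
        hl_biotrans_airbreather=logu(*b["hl_biotrans_airbreather"]),
        c_tox_autotroph=logu(*b["c_tox_autotroph"]),
        c_tox_invertebrate=logu(*b["c_tox_invertebrate"]),
        c_tox_fish=logu(*b["c_tox_fish"]),
        ir_threshold=0.15,
    )


def random_scenario(rng: np.random.Generator, substance_id: str = "RND") -> EmissionScenario:
    moe = rng.dirichlet((1.0, 1.0, 1.0))
    rate = float(np.exp(rng.uniform(np.log(1.14e-13), np.log(1.5e3))))
    return EmissionScenario(substance_id, rate, tuple(moe))
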