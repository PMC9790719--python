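"""Level III fate engine: capacities, D values, steady state, vegetation."""

import copy

import numpy as np
import pytest

from fugrisk.environment import load_environment
from fugrisk.fate import (
    AIR,
    SEDIMENT,
    SOIL,
    WATER,
    FateError,
    R_GAS,
    compute_capacities,
    compute_transport_coefficients,
    solve_steady_state,
    vegetation_exposure,
)
from fugrisk.inventory import EmissionScenario

from conftest import random_chemical, random_scenario
from oracles import ode_steady_state


@pytest.fixture(scope="module")
def chem():
    rng = np.random.default_rng(100)
    return random_chemical(rng, "FATE-CHEM")


class TestCapacities:
    def test_air_capacity_is_inverse_rt(self, env, chem):
        z = compute_capacities(chem, env)
        assert z.z_air_pure == pytest.approx(1.0 / (R_GAS * 298.15), rel=1e-12)
        assert z.z_air_pure == pytest.approx(4.034e-4, rel=1e-3)

    def test_unit_kaw_equalizes_air_and_water(self, env, chem):
        import dataclasses
        chem1 = dataclasses.replace(chem, log_kaw=0.0)
        z = compute_capacities(chem1, env)
        assert z.z_water_pure == pytest.approx(z.z_air_pure, rel=1e-12)

    def test_bulk_equals_weighted_sum(self, env):
        """Bulk Z equals an independent volume-fraction-weighted resum."""
        rng = np.random.default_rng(2)
        for i in range(30):
            c = random_chemical(rng, f"C{i}")
            z = compute_capacities(c, env)
            expected = [
                (1 - env.vf_aerosol) * z.z_air_pure + env.vf_aerosol * z.z_aerosol,
                (1 - env.vf_susp_solids - env.vf_biota) * z.z_water_pure
                + env.vf_susp_solids * z.z_susp_solids + env.vf_biota * z.z_biota,
                env.vf_soil_air * z.z_air_pure + env.vf_soil_water * z.z_water_pure
                + env.vf_soil_solids * z.z_soil_solids,
                env.vf_sed_water * z.z_water_pure + env.vf_sed_solids * z.z_sed_solids,
            ]
            assert z.bulk == pytest.approx(expected, rel=1e-12)


class TestTransport:
    def test_reaction_rate_constant(self, env, chem):
        import dataclasses
        c = dataclasses.replace(chem, hl_air=693147.0)  # k = ln2/HL ~ 1e-6 /h
        z = compute_capacities(c, env)
        t = compute_transport_coefficients(c, env, z)
        expected = env.volume_air * z.bulk[AIR] * (np.log(2) / 693147.0)
        assert t.d_reaction[AIR] == pytest.approx(expected, rel=1e-12)
        assert t.d_reaction[AIR] == pytest.approx(env.volume_air * z.bulk[AIR] * 1e-6,
                                                  rel=1e-6)

    def test_zero_precipitation_kills_wet_pathways(self, chem):
        env0 = load_environment(rain_rate=0.0)
        z = compute_capacities(chem, env0)
        t = compute_transport_coefficients(chem, env0, z)
        env = load_environment()
        zr = compute_capacities(chem, env)
        tr = compute_transport_coefficients(chem, env, zr)
        # with rain off, air->water reduces to diffusion + dry deposition only
        d_vw = env0.area_water / (
            1.0 / (env0.mtc_air_side * z.z_air_pure)
            + 1.0 / (env0.mtc_water_side * z.z_water_pure)
        )
        d_dry = env0.area_water * env0.dry_dep_velocity * env0.vf_aerosol * z.z_aerosol
        assert t.d_inter[AIR, WATER] == pytest.approx(d_vw + d_dry, rel=1e-12)
        assert t.d_inter[AIR, WATER] < tr.d_inter[AIR, WATER]

    def test_deposition_paths_are_one_way(self, env):
        """Runoff, burial and particle deposition have no reverse entries."""
        rng = np.random.default_rng(8)
        for i in range(20):
            c = random_chemical(rng, f"C{i}")
            z = compute_capacities(c, env)
            t = compute_transport_coefficients(c, env, z)
            assert t.d_inter[WATER, SOIL] == 0.0  # nothing flows water->soil
            assert t.d_inter[SOIL, SEDIMENT] == 0.0
            assert t.d_inter[SEDIMENT, SOIL] == 0.0
            assert t.d_inter[SEDIMENT, AIR] == 0.0
            assert t.d_inter[AIR, SEDIMENT] == 0.0
            assert t.d_burial >= 0.0
            # particle deposition makes air->water exceed water->air diffusion
            assert t.d_inter[AIR, WATER] >= t.d_inter[WATER, AIR]
            assert np.all(t.d_inter >= 0) and np.all(t.d_reaction > 0)


class TestSteadyState:
    def test_single_compartment_closed_form(self, env, chem):
        """With intermedia transport and advection off, air emission gives
        f_air = E/D_reaction and P_OV = 1/k_air."""
        z = compute_capacities(chem, env)
        t = compute_transport_coefficients(chem, env, z)
        t = copy.deepcopy(t)
        t.d_inter[:] = 0.0
        t.d_advection[:] = 0.0
        t.d_burial = 0.0
        sc = EmissionScenario(chem.substance_id, 1.0, (1.0, 0.0, 0.0))
        res = solve_steady_state(chem, env, sc, z=z, transport=t)
        e_mol = 1000.0 / chem.molar_mass
        assert res.fugacities[AIR] == pytest.approx(
            e_mol / t.d_reaction[AIR], rel=1e-12)
        assert res.fugacities[[WATER, SOIL, SEDIMENT]] == pytest.approx([0, 0, 0])
        k_air = np.log(2) / chem.hl_air
        assert res.p_ov_reaction_h == pytest.approx(1.0 / k_air, rel=1e-9)

    def test_zero_emission_all_zero(self, env, chem):
        sc = EmissionScenario(chem.substance_id, 0.0, (1.0, 0.0, 0.0))
        res = solve_steady_state(chem, env, sc)
        assert np.all(res.fugacities == 0) and np.all(res.mass_kg == 0)
        assert sum(res.loss_budget_kg_h.values()) == 0.0

    def test_singular_balance_raises(self, env, chem):
        z = compute_capacities(chem, env)
        t = compute_transport_coefficients(chem, env, z)
        t = copy.deepcopy(t)
        t.d_inter[:] = 0.0
        t.d_advection[:] = 0.0
        t.d_burial = 0.0
        t.d_reaction[:] = 0.0
        sc = EmissionScenario(chem.substance_id, 1.0, (1.0, 0.0, 0.0))
        with pytest.raises(FateError, match="singular|no physical"):
            solve_steady_state(chem, env, sc, z=z, transport=t)

    def test_mass_balance_closure(self, env):
        """Total loss equals total emission for random chemicals/scenarios."""
        rng = np.random.default_rng(4)
        for i in range(50):
            c = random_chemical(rng, f"C{i}")
            sc = random_scenario(rng, c.substance_id)
            res = solve_steady_state(c, env, sc)
            assert sum(res.loss_budget_kg_h.values()) == pytest.approx(
                sc.total_rate, rel=1e-9)
            assert res.mass_fraction_pct.sum() == pytest.approx(100.0, abs=1e-9)

    def test_linearity_in_emission(self, env, chem):
        sc1 = EmissionScenario(chem.substance_id, 0.7, (0.5, 0.3, 0.2))
        sc2 = EmissionScenario(chem.substance_id, 1.4, (0.5, 0.3, 0.2))
        r1 = solve_steady_state(chem, env, sc1)
        r2 = solve_steady_state(chem, env, sc2)
        assert r2.fugacities == pytest.approx(2 * r1.fugacities, rel=1e-12)
        assert r2.mass_kg == pytest.approx(2 * r1.mass_kg, rel=1e-12)
        assert r2.p_ov_reaction_h == pytest.approx(r1.p_ov_reaction_h, rel=1e-12)
        assert r2.mass_fraction_pct == pytest.approx(r1.mass_fraction_pct, rel=1e-9)

    def test_matches_ode_integration(self, env):
        """Linear solve agrees with brute-force dynamic integration."""
        rng = np.random.default_rng(17)
        for i in range(10):
            c = random_chemical(rng, f"C{i}")
            sc = random_scenario(rng, c.substance_id)
            res = solve_steady_state(c, env, sc)
            f_ode = ode_steady_state(env, c, res.capacities, res.transport,
                                     res.emission_mol_h, res.fugacities)
            scale = np.maximum(res.fugacities, res.fugacities.max() * 1e-250)
            assert np.max(np.abs(f_ode - res.fugacities) / scale) < 1e-6

    def test_level2_limit(self, env):
        """Inflating the intermedia mass-transfer coefficients a million-fold
        drives the system to its equilibrium (equifugacity) limit."""
        from fugrisk.synth import median_like_record

        chem = median_like_record()
        env2 = env.replace(**{f: getattr(env, f) * 1e6 for f in (
            "mtc_air_side", "mtc_water_side", "mtc_soil_air",
            "mtc_soil_water", "mtc_sed_water")})
        sc = EmissionScenario(chem.substance_id, 1.0, (1.0, 0.0, 0.0))
        res = solve_steady_state(chem, env2, sc)
        f = res.fugacities
        assert f.max() / f.min() == pytest.approx(1.0, abs=1e-3)

    def test_persistence_identity_and_monotonicity(self, env):
        rng = np.random.default_rng(21)
        import dataclasses
        for i in range(20):
            c = random_chemical(rng, f"C{i}")
            sc = random_scenario(rng, c.substance_id)
            res = solve_steady_state(c, env, sc)
            react = sum(v for k, v in res.loss_budget_kg_h.items()
                        if k.startswith("reaction"))
            assert res.p_ov_reaction_h * react == pytest.approx(
                res.mass_kg.sum(), rel=1e-9)
            fld = ("hl_air", "hl_water", "hl_soil", "hl_sediment")[i % 4]
            longer = dataclasses.replace(c, **{fld: getattr(c, fld) * 3.0})
            res2 = solve_steady_state(longer, env, sc)
            assert res2.p_ov_reaction_h >= res.p_ov_reaction_h * (1 - 1e-12)


class TestVegetation:
    def test_zero_fugacity_zero_vegetation(self, env, chem):
        sc = EmissionScenario(chem.substance_id, 0.0, (1.0, 0.0, 0.0))
        res = solve_steady_state(chem, env, sc)
        veg = vegetation_exposure(chem, env, res)
        assert veg.foliage_mol_m3 == 0.0 and veg.root_mol_kg == 0.0

    def test_equilibrium_limit(self, env, chem):
        """Foliage at equilibrium with air when deposition and loss are off."""
        sc = EmissionScenario(chem.substance_id, 1.0, (1.0, 0.0, 0.0))
        res = solve_steady_state(chem, env, sc)
        veg = vegetation_exposure(chem, env, res,
                                  disable_particles=True, disable_loss=True)
        z = res.capacities
        assert veg.foliage_mol_m3 == pytest.approx(
            z.z_foliage * res.fugacities[AIR], rel=1e-12)

    def test_foliage_matches_one_compartment_integration(self, env):
        """Foliage steady state equals a brute-force ODE solve of its own
        one-compartment balance."""
        from scipy.integrate import solve_ivp

        rng = np.random.default_rng(33)
        for i in range(5):
            c = random_chemical(rng, f"C{i}")
            sc = EmissionScenario(c.substance_id, 1.0, (1.0, 0.0, 0.0))
            res = solve_steady_state(c, env, sc)
            veg = vegetation_exposure(c, env, res)
            z = res.capacities
            a_fol = env.area_soil * env.leaf_area_index
            v_fol = env.area_soil * env.foliage_volume_per_area
            d_gas = a_fol * env.mtc_foliage * z.z_air_pure
            d_part = (env.area_soil * env.particle_interception
                      * (env.rain_rate * env.scavenging_ratio + env.dry_dep_velocity)
                      * env.vf_aerosol * z.z_aerosol)
            d_loss = v_fol * z.z_foliage * env.foliage_loss_rate
            vz = v_fol * z.z_foliage
            f_air = res.fugacities[AIR]

            def rhs(_t, y):
                return ((d_gas + d_part) * f_air - (d_gas + d_loss) * y[0]) / vz

            tau = vz / (d_gas + d_loss)
            sol = solve_ivp(rhs, (0, 60 * tau), [0.0], method="LSODA",
                            rtol=1e-10, atol=1e-14 * max(veg.foliage_mol_m3 / z.z_foliage, 1e-280))
            f_fol = sol.y[0, -1]
            assert z.z_foliage * f_fol == pytest.approx(veg.foliage_mol_m3, rel=1e-6)
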