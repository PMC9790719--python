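"""Independent numerical oracles used by the test suite.

These deliberately avoid the code paths they check: the fate oracle
integrates the dynamic mass balance as an ODE instead of solving the
steady-state linear system; the food-web oracle assembles and solves the
simultaneous linear system instead of sweeping in trophic order.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from fugrisk.bioacc import BioaccParams, Receptor, receptor_steady_state
from fugrisk.fate import MediaConcentrations, balance_matrix


def ode_steady_state(env, chem, z, transport, e_mol_h, f_reference):
    """Steady state by explicit time integration of the dynamic balance.

    dy/dt = M^-1 (E - A y) with M = diag(V Z_bulk), integrated from zero
    until the relative change over a 20% time extension is < 1e-10.
    ``f_reference`` is used only to scale the integrator's absolute
    tolerance per compartment.
    """
    a = balance_matrix(transport)
    volumes = np.array([env.volume_air, env.volume_water,
                        env.volume_soil, env.volume_sediment])
    m = volumes * z.bulk
    minv = 1.0 / m

    def rhs(_t, y):
        return minv * (e_mol_h - a @ y)

    jac = -minv[:, None] * a
    rates = np.real(np.linalg.eigvals(minv[:, None] * a))
    t_end = 40.0 / max(rates.min(), 1e-300)
    atol = 1e-13 * np.maximum(np.abs(f_reference), 1e-280)
    sol = solve_ivp(rhs, (0.0, 1.2 * t_end), np.zeros(4), method="Radau",
                    jac=lambda _t, _y: jac, rtol=1e-10, atol=atol,
                    t_eval=[t_end, 1.2 * t_end])
    assert sol.success, sol.message
    y1, y2 = sol.y[:, 0], sol.y[:, 1]
    scale = np.maximum(np.abs(y2), atol / 1e-3)
    assert np.max(np.abs(y2 - y1) / scale) < 1e-10, "integration not converged"
    return y2


def zero_media() -> MediaConcentrations:
    return MediaConcentrations(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


def unit_prey(receptor_id: str):
    """A prey result with unit whole-body concentration (probing vector)."""
    from fugrisk.bioacc import ReceptorResult

    return ReceptorResult(receptor_id, conc_mol_kg=1.0, conc_mmol_l=0.0,
                          conc_mg_kg=0.0, intake_mg_kg_day=None, baf_l_kg=0.0)


def food_web_linear_solve(chem, roster: list[Receptor], media, params: BioaccParams):
    """Solve all receptor balances simultaneously.

    Exploits linearity: per receptor, the media-driven input b_r comes from
    solving with all prey at zero, and the diet-transfer coefficient T_rj
    from probing with prey j at unit concentration under zero media.  The
    full system (I - T) c = b is then solved at once with numpy.
    """
    ids = [r.receptor_id for r in roster]
    idx = {rid: i for i, rid in enumerate(ids)}
    n = len(ids)
    b = np.zeros(n)
    t = np.zeros((n, n))
    zmedia = zero_media()
    from fugrisk.bioacc import ReceptorResult

    for r in roster:
        prey0 = {d: ReceptorResult(d, 0.0, 0.0, 0.0, None, 0.0)
                 for d in r.diet if d in idx}
        b[idx[r.receptor_id]] = receptor_steady_state(
            chem, r, media, prey0, params).conc_mol_kg
        for d in r.diet:
            if d not in idx:
                continue
            probe = dict(prey0)
            probe[d] = unit_prey(d)
            c = receptor_steady_state(chem, r, zmedia, probe, params).conc_mol_kg
            t[idx[r.receptor_id], idx[d]] = c
    conc = np.linalg.solve(np.eye(n) - t, b)
    return dict(zip(ids, conc))
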