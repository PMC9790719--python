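"""Level III fate of one chemical in the evaluative region.

Solves the steady-state fugacity balance for a typical (median-parameter)
organic substance emitted to air at 1 kg/h, and prints where the chemical
ends up, how long it persists, and how it is lost.
"""

from fugrisk import EmissionScenario, load_environment, solve_steady_state
from fugrisk.fate import COMPARTMENTS
from fugrisk.synth import median_like_record

env = load_environment()  # 100 000 km^2, 90% land / 10% water
chem = median_like_record()
scenario = EmissionScenario(chem.substance_id, total_rate=1.0,
                            moe_fractions=(1.0, 0.0, 0.0))  # 1 kg/h to air

result = solve_steady_state(chem, env, scenario)

print(f"substance: {chem.name}  (log KOW {chem.log_kow}, log KAW {chem.log_kaw})")
print(f"emission: {scenario.total_rate} kg/h to air\n")
print(f"{'compartment':<12} {'fugacity (Pa)':>14} {'conc (mg/L)':>12} "
      f"{'mass (kg)':>12} {'share (%)':>10}")
for i, name in enumerate(COMPARTMENTS):
    print(f"{name:<12} {result.fugacities[i]:>14.3e} {result.conc_mg_l[i]:>12.3e} "
          f"{result.mass_kg[i]:>12.3e} {result.mass_fraction_pct[i]:>10.2f}")

print(f"\noverall reaction persistence P_OV: {result.p_ov_reaction_days:.1f} days")
print(f"overall residence time (incl. advection/burial): "
      f"{result.residence_time_overall_h / 24:.1f} days")
print("\nloss budget (kg/h) — sums to the emission rate at steady state:")
for proc, rate in result.loss_budget_kg_h.items():
    print(f"  {proc:<18} {rate:.3e}")

# The mass shares say which media matter for exposure (here mostly air and
# soil); P_OV is the average time a molecule survives before degradation.
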