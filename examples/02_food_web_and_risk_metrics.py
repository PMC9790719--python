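"""Food-web bioaccumulation and the four screening metrics.

Contrasts two archetype substances — a high-volume, rapidly degraded
solvent and a trace-volume persistent/bioaccumulative group substance —
under the same emission scenarios, printing receptor concentrations and
the EAF / HAF / RCR / RAF screening metrics for each.
"""

from fugrisk import EmissionScenario, compute_haf_raf, load_environment, load_roster
from fugrisk.metrics import run_receptors
from fugrisk.synth import dioxin_like_record, solvent_like_record

env = load_environment()
roster, params = load_roster()

for chem, rate in ((solvent_like_record(), 2283.1),   # ~20 000 t/yr
                   (dioxin_like_record(), 1.14e-8)):  # ~0.1 kg/yr
    scenario = EmissionScenario(chem.substance_id, rate, (1.0, 0.0, 0.0))
    fate, receptors = run_receptors(chem, env, roster, params, scenario)
    metrics = compute_haf_raf(chem, env, roster, params, scenario)

    print(f"=== {chem.name} — {rate:.4g} kg/h to air ===")
    print(f"  P_OV {fate.p_ov_reaction_days:.1f} d | "
          f"fish BAF {receptors['piscivorous_fish'].baf_l_kg:.3g} L/kg")
    print(f"  EAF {metrics.eaf:.3g} (top receptor: {metrics.eaf_receptor})")
    print(f"  HAF {metrics.haf:.3g} (most sensitive at unit emission: "
          f"{metrics.haf_receptor})")
    print(f"  RAF {metrics.raf:.3g} (most sensitive receptor: "
          f"{metrics.most_sensitive_receptor})")
    print("  per-receptor risk ratios (actual emissions):")
    for rid, rcr in sorted(metrics.rcr.items(), key=lambda kv: -kv[1])[:4]:
        print(f"    {rid:<22} RCR {rcr:.3g}")
    print()

# EAF and HAF are computed at a unit 1 kg/h emission, so they express a
# chemical's exposure and hazard *potential* regardless of how much is
# actually released; RAF folds in the actual rate.  The persistent
# archetype dominates the potentials, the solvent dominates only once its
# enormous actual tonnage is applied.
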