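"""Why total quantity can rise while total risk stays flat.

Builds the mode-of-entry drift fixture: a semivolatile foliage-binding
substance whose tonnage grows 10%/yr while its releases shift from air
toward land, next to an identical-tonnage counterfactual that keeps the
original split.  Prints risk-per-tonne by compartment of entry and the
ordinary-least-squares trend slopes for both inventories.
"""

from fugrisk import load_environment, load_roster, risk_per_tonne, timeseries_totals
from fugrisk.synth import moe_drift_fixture, semivolatile_like_record

env = load_environment()
roster, params = load_roster()

chem = semivolatile_like_record()
print(f"risk per tonne of {chem.substance_id} by compartment of entry:")
for comp in ("air", "water", "soil"):
    print(f"  {comp:<6} {risk_per_tonne(chem, comp, env, roster, params):.3e}")

cfg, db, drift_records, counter_records = moe_drift_fixture(seed=1)
ts_d, slopes_d = timeseries_totals(db, drift_records, env, roster, params)
ts_c, slopes_c = timeseries_totals(db, counter_records, env, roster, params)

print("\nyear   tonnes (drift)   total RCR (drift)   total RCR (no drift)")
merged = ts_d.merge(ts_c, on="year", suffixes=("_d", "_c"))
for _, row in merged.iterrows():
    print(f"{int(row['year'])}  {row['total_quantity_tonnes_d']:>14.0f}"
          f"  {row['total_rcr_d']:>18.3f}  {row['total_rcr_c']:>20.3f}")

print(f"\nquantity slope: {slopes_d['quantity_slope_tonnes_per_year']:+.1f} t/yr "
      "(identical in both inventories)")
print(f"risk slope with drift:        {slopes_d['rcr_slope_per_year']:+.4f} /yr")
print(f"risk slope, no-drift control: {slopes_c['rcr_slope_per_year']:+.4f} /yr")
print("\nBecause a tonne released to land carries orders of magnitude less "
      "risk than a tonne to air for this substance, the shift in receiving "
      "compartment flattens (here even reverses) the risk trend while the "
      "quantity trend keeps climbing.")
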