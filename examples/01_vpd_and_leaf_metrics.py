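"""Vapour-pressure physics and the leaf-level response statistics.

Builds a tiny hand-made steady-state table for one plant and computes
the transpiration reduction (phi_E), the limitation of assimilation and
the stomatal reduction (phi_stom).
"""

import numpy as np
import pandas as pd

from vpdpheno import vpd
from vpdpheno.leaf_metrics import fit_stomatal_reduction, limitation_of_a, phi_e

# The humidity step protocol: VPD is set by lowering RH at constant
# temperature.  At 36 degC and 87% RH the chamber VPD is 0.77 kPa.
for rh in (87, 78, 68, 62, 56):
    print(f"RH {rh:2d}% at 36 degC -> VPD {vpd(36.0, rh / 100.0):.2f} kPa")

# One plant measured at three VPD levels.  E rises linearly over the
# first two levels; at the third it falls short of the extrapolation.
table = pd.DataFrame({
    "plant": "p1", "accession": "demo",
    "level": [0, 1, 2],
    "vpd": [1.0, 2.0, 3.0],
    "gs": [0.40, 0.33, 0.29],
    "e": [2.0, 4.0, 4.5],
    "a": [20.0, 18.0, 16.0],
    "iwue": [50.0, 54.5, 55.2],
    "missing": False,
})

pe = phi_e(table, baseline_levels=(0, 1), target_levels=[2])
print(f"\nE predicted at 3.0 kPa: {pe['e_pred'].iloc[0]:.1f} mmol m-2 s-1, "
      f"measured {pe['e_meas'].iloc[0]:.1f}")
print(f"transpiration reduction phi_E = {pe['phi_e'].iloc[0]:.2f} "
      "(the plant sheds 25% of the water loss a constant-conductance leaf would have)")

al = limitation_of_a(table)
print(f"limitation of A at the top level = "
      f"{al[al['level'] == 2]['limitation'].iloc[0]:.2f} "
      "(photosynthesis forgone to stomatal closure)")

a, phi_stom, r2 = fit_stomatal_reduction(table["vpd"], table["gs"])
print(f"stomatal decline: gs = {a:.3f} - {phi_stom:.3f} ln(VPD)  (R2 = {r2:.3f})")
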