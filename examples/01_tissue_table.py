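"""Tissue dielectric/thermal constants and derived perfusion coefficients.

Prints the 1 GHz breast-tissue property table used throughout the planning
chain, including the volumetric Pennes perfusion coefficient
rho_b*C_b*rho*HTR (W/m^3/K) derived from the per-mass heat transfer rate.
The tumor row carries the muscle constants; its perfusion is temperature
dependent and handled by the bioheat solver instead of a fixed column.
"""

from htplan import build_tissue_table, perfusion_coefficient, tissue_table_frame

table = build_tissue_table()
print(tissue_table_frame(table).to_string(float_format=lambda v: f"{v:g}"))

print("\nPerfusion coefficients (W/m^3/K):")
for name in ("gland", "skin", "muscle", "breast_fat", "fat", "blood"):
    print(f"  {name:11s} {perfusion_coefficient(table[name]):12.1f}")
print("Each value is the linear Pennes heat-sink strength per kelvin of")
print("tissue-blood temperature difference; blood's own entry is the")
print("self-consistency reference, not a spatial tissue.")
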