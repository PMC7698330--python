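"""Published reference settings for the eight-dipole array.

The bundled table lists the optimized per-antenna input powers and phases
for spherical tumors of radius 2–12 mm from the original anatomical-phantom
study this package's planning pipeline follows.  It serves as a schema and
convention reference (the power budget Σ P_i = 8 W; antenna 8 as the phase
reference): the exact values are specific to that undistributed anatomical
model and are not reproduced by the synthetic phantoms here.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["reference_excitations"]


def reference_excitations() -> pd.DataFrame:
    """Reference optimized array settings, one row per (radius, antenna).

    Columns: tumor_radius_mm, antenna (1-8), power_W, phase_deg.
    """
    with resources.files("htplan.data").joinpath(
        "reference_excitations.csv"
    ).open() as fh:
        return pd.read_csv(fh)
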