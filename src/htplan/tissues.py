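"""Tissue dielectric and thermal properties at 1 GHz.

Property values follow the IT'IS database entries for female breast tissues
at the 1 GHz operating frequency of the dipole array.  The tumor shares the
muscle dielectric and thermal constants; its blood perfusion is
temperature-dependent (see :mod:`htplan.bioheat`) and therefore carries no
fixed heat-transfer rate here.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import pandas as pd

#: arterial blood density (kg/m^3) and specific heat (J/kg/K) used in the
#: Pennes perfusion sink rho_b * C_b * rho * HTR * (T_b - T)
RHO_BLOOD = 1050.0
C_BLOOD = 3617.0

#: conversion mL/min/kg -> m^3/s/kg
_HTR_SI = 1e-6 / 60.0


@dataclass(frozen=True)
class TissueProperties:
    """Dielectric + thermal constants for one tissue.

    Attributes
    ----------
    eps_r : relative permittivity (dimensionless, >= 1)
    sigma : electrical conductivity (S/m)
    rho : mass density (kg/m^3)
    C : specific heat (J/kg/K)
    k : thermal conductivity (W/m/K)
    HTR : heat transfer rate, i.e. blood perfusion per tissue mass
        (mL/min/kg); ``None`` marks a temperature-dependent perfusion
        (the tumor).
    HGR : metabolic heat generation rate (W/kg)
    """

    name: str
    eps_r: float
    sigma: float
    rho: float
    C: float
    k: float
    HTR: float | None
    HGR: float

    def __post_init__(self) -> None:
        if self.eps_r < 1:
            raise ValueError(f"{self.name}: eps_r must be >= 1")
        for f in ("sigma", "rho", "C", "k", "HGR"):
            if getattr(self, f) < 0:
                raise ValueError(f"{self.name}: {f} must be >= 0")
        if self.HTR is not None and self.HTR < 0:
            raise ValueError(f"{self.name}: HTR must be >= 0")

    @property
    def perfusion_temperature_dependent(self) -> bool:
        return self.HTR is None


def build_tissue_table() -> dict[str, TissueProperties]:
    """Return the seven-tissue property table (1 GHz constants).

    The tumor entry copies the muscle constants; its HTR is ``None``
    because tumor perfusion follows the nonlinear temperature model.
    """
    t = {
        "blood": TissueProperties("blood", 61.06, 1.583, 1050, 3617, 0.517, 10000, 0.0),
        "breast_fat": TissueProperties("breast_fat", 5.41, 0.053, 911, 2348, 0.209, 47, 0.728),
        "gland": TissueProperties("gland", 59.47, 1.079, 1041, 2960, 0.334, 150, 2.323),
        "fat": TissueProperties("fat", 11.29, 0.116, 911, 2348, 0.211, 33, 0.507),
        "muscle": TissueProperties("muscle", 54.81, 0.978, 1090, 3421, 0.495, 37, 0.906),
        "skin": TissueProperties("skin", 40.94, 0.900, 1109, 3391, 0.372, 106, 1.648),
    }
    m = t["muscle"]
    t["tumor"] = TissueProperties("tumor", m.eps_r, m.sigma, m.rho, m.C, m.k, None, m.HGR)
    return t


def perfusion_coefficient(
    props: TissueProperties, rho_b: float = RHO_BLOOD, C_b: float = C_BLOOD
) -> float:
    """Volumetric perfusion coefficient rho_b*C_b*rho*HTR_SI (W/m^3/K).

    HTR is converted from mL/min/kg to m^3/s/kg (factor 1e-6/60).  Raises
    for tissues whose perfusion is temperature-dependent (tumor) or
    negative.
    """
    if props.HTR is None:
        raise ValueError(
            f"{props.name}: perfusion is temperature-dependent; use bioheat.tumor_perfusion"
        )
    if props.HTR < 0:
        raise ValueError(f"{props.name}: negative HTR")
    return rho_b * C_b * props.rho * props.HTR * _HTR_SI


def tissue_table_frame(table: dict[str, TissueProperties] | None = None) -> pd.DataFrame:
    """Tissue table as a DataFrame, with the derived perfusion column."""
    table = table if table is not None else build_tissue_table()
    rows = []
    for name, p in table.items():
        d = asdict(p)
        d["perfusion_W_m3_K"] = (
            None if p.HTR is None else perfusion_coefficient(p)
        )
        rows.append(d)
    return pd.DataFrame(rows).set_index("name")


def export_tissue_csv(path, table: dict[str, TissueProperties] | None = None) -> None:
    tissue_table_frame(table).to_csv(path)
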