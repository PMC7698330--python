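"""End-to-end planning pipeline: phantom → unit fields → quadratic forms →
optimal excitation → SAR/heat-source maps → transient thermal profiles,
swept over tumor radii.

The eight unit fields are solved on one shared FDTD domain so they
superpose exactly.  Because the tumor carries muscle dielectrics (distinct
from gland), the faithful mode re-solves the fields for every tumor
radius; the fast mode solves them once for a reference radius and reuses
them across the sweep (a documented approximation that only perturbs the
dielectric contrast of the tumor sphere).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .bioheat import ThermalConfig, simulate_treatment
from .dipole import ArrayGeometry, DipoleSpec, place_array
from .fdtd import ComplexFieldVolume, SolverConfig, _Domain, fdtd_unit_field
from .optimize import OptimizationProblem, optimal_excitation, sar_ratio
from .phantom import VoxelPhantom, generate_breast_phantom
from .sar import ExcitationVector, build_quadratic_form, sar_map, sar_vol

__all__ = [
    "PipelineConfig",
    "RadiusResult",
    "SweepResult",
    "compute_unit_fields",
    "build_problem",
    "plan_single_radius",
    "run_radius_sweep",
    "extract_profile",
    "report",
]


@dataclass
class PipelineConfig:
    """One document controlling the whole study; YAML round-trips."""

    spacing: float = 3.0
    composition_class: str = "HD"
    phantom_seed: int = 0
    breast_radius: float = 70.0
    skin_thickness: float = 2.0
    tumor_center: tuple = (0.0, -12.0, 12.0)
    tumor_radii: tuple = (2.0, 4.0, 6.0, 8.0, 10.0, 12.0)
    n_antennas: int = 8
    ring_radius: float = 100.0
    frequency: float = 1.0e9
    total_power: float = 8.0
    reuse_fields: bool = False       # fast mode: one EM solve per sweep
    optimizer_seed: int = 0
    exposure_duration: float = 1800.0
    cooldown_duration: float = 600.0
    h_convective: float = 10.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("tumor_center", "tumor_radii"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in asdict(self).items()},
                fh, sort_keys=True,
            )

    def solver_config(self) -> SolverConfig:
        return SolverConfig(spacing=self.spacing)

    def thermal_config(self) -> ThermalConfig:
        return ThermalConfig(
            exposure_duration=self.exposure_duration,
            cooldown_duration=self.cooldown_duration,
            h=self.h_convective,
        )

    def make_phantom(self, tumor_radius: float) -> VoxelPhantom:
        return generate_breast_phantom(
            spacing=self.spacing,
            breast_radius=self.breast_radius,
            skin_thickness=self.skin_thickness,
            tumor_radius=tumor_radius,
            tumor_center=self.tumor_center,
            composition_class=self.composition_class,
            seed=self.phantom_seed,
        )


@dataclass
class RadiusResult:
    tumor_radius: float
    excitation: ExcitationVector
    sar_ratio: float
    sar_vol_tumor: float             # W/kg at the optimal excitation
    sar_vol_tumor_uniform: float     # W/kg at the uniform excitation
    sar_max_tumor: float             # W/kg peak within the tumor
    t: np.ndarray
    T_center: np.ndarray
    T_tumor_max: np.ndarray
    T_end_center: float
    T_end_tumor_max: float
    per_tissue_max: dict
    profiles: dict                   # axis -> (offsets_mm, Q, T)
    db_slice: np.ndarray             # xy dB SAR slice through the tumor


@dataclass
class SweepResult:
    config: PipelineConfig
    results: list[RadiusResult] = field(default_factory=list)

    def by_radius(self) -> dict[float, RadiusResult]:
        return {r.tumor_radius: r for r in self.results}


def compute_unit_fields(
    phantom: VoxelPhantom,
    config: PipelineConfig,
    solver: SolverConfig | None = None,
    verbose: bool = False,
) -> list[ComplexFieldVolume]:
    """Solve the unit (1 W) field of every array element on one shared
    domain."""
    solver = solver or config.solver_config()
    geometry = ArrayGeometry(config.n_antennas, config.ring_radius)
    proto = DipoleSpec((0.0, 0.0, 0.0), frequency=config.frequency)
    dipoles = place_array(geometry, proto, phantom=phantom)
    dom = _Domain(phantom, dipoles, solver)
    fields = []
    for n, dip in enumerate(dipoles):
        if verbose:
            print(f"  antenna {n + 1}/{len(dipoles)}: FDTD solve ...", flush=True)
        fields.append(
            fdtd_unit_field(phantom, dip, solver, antenna_index=n, domain=dom)
        )
    return fields


def build_problem(
    phantom: VoxelPhantom,
    fields: list[ComplexFieldVolume],
    total_power: float = 8.0,
) -> OptimizationProblem:
    """Quadratic forms over the tumor and all healthy (non-tumor, non-air)
    tissue, as an optimization problem."""
    from .fdtd import extract_on_phantom

    tumor = phantom.mask("tumor")
    healthy = (phantom.labels != 0) & ~tumor
    if not tumor.any():
        raise ValueError("phantom has no tumor voxels")
    sigma = phantom.property_grid("sigma")
    rho = phantom.property_grid("rho", default=1.0)
    E = [extract_on_phantom(f, phantom) for f in fields]

    def form(mask, rid):
        F = np.stack([e[:, mask] for e in E])
        return build_quadratic_form(
            None, None, sigma[mask], rho[mask], region_id=rid, field_arrays=F
        )

    return OptimizationProblem(
        H_tumor=form(tumor, "tumor"),
        H_healthy=form(healthy, "healthy"),
        total_power=total_power,
    )


def extract_profile(volume: np.ndarray, axis: str, phantom: VoxelPhantom,
                    through=None):
    """1-D profile of a phantom-grid volume along x or y through the tumor
    center; offsets are mm relative to the center."""
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    center = through if through is not None else phantom.tumor_center
    ci, cj, ck = phantom.index_of(center)
    ax = 0 if axis == "x" else 1
    idx = [ci, cj, ck]
    n = phantom.shape[ax]
    values = np.empty(n)
    for m in range(n):
        idx[ax] = m
        values[m] = volume[tuple(idx)]
    coords = phantom.voxel_centers(ax)
    offsets = coords - coords[[ci, cj, ck][ax]]
    return offsets, values


def plan_single_radius(
    config: PipelineConfig,
    tumor_radius: float,
    fields: list[ComplexFieldVolume] | None = None,
    phantom: VoxelPhantom | None = None,
    verbose: bool = False,
) -> RadiusResult:
    """Full planning chain for one tumor radius."""
    phantom = phantom or config.make_phantom(tumor_radius)
    if fields is None:
        fields = compute_unit_fields(phantom, config, verbose=verbose)
    problem = build_problem(phantom, fields, config.total_power)
    exc, ratio = optimal_excitation(problem)
    uniform = ExcitationVector.uniform(
        config.n_antennas, config.total_power / config.n_antennas
    )
    sar, db = sar_map(fields, exc, phantom)
    tumor = phantom.mask("tumor")
    rho = phantom.property_grid("rho", default=0.0)
    Q = rho * sar  # W/m^3
    sim = simulate_treatment(phantom, Q, config.thermal_config())
    ci, cj, ck = phantom.index_of(phantom.tumor_center)
    off_x, q_x = extract_profile(Q, "x", phantom)
    off_y, q_y = extract_profile(Q, "y", phantom)
    _, t_x = extract_profile(sim["T_end_exposure"], "x", phantom)
    _, t_y = extract_profile(sim["T_end_exposure"], "y", phantom)
    return RadiusResult(
        tumor_radius=tumor_radius,
        excitation=exc,
        sar_ratio=ratio,
        sar_vol_tumor=sar_vol(problem.H_tumor, exc),
        sar_vol_tumor_uniform=sar_vol(problem.H_tumor, uniform),
        sar_max_tumor=float(sar[tumor].max()),
        t=sim["t"],
        T_center=sim["T_center"],
        T_tumor_max=sim["T_tumor_max"],
        T_end_center=float(sim["T_end_exposure"][ci, cj, ck]),
        T_end_tumor_max=float(sim["T_end_exposure"][tumor].max()),
        per_tissue_max=sim["per_tissue_max_end_exposure"],
        profiles={"x": (off_x, q_x, t_x), "y": (off_y, q_y, t_y)},
        db_slice=db[:, :, ck],
    )


def run_radius_sweep(config: PipelineConfig, verbose: bool = False) -> SweepResult:
    """Run the planning chain over the configured tumor radii.

    With ``reuse_fields`` the EM solve is done once on the largest-radius
    phantom and shared across the sweep (fast, approximate); otherwise the
    fields are re-solved per radius.
    """
    sweep = SweepResult(config=config)
    shared_fields = None
    if config.reuse_fields:
        ref_radius = max(config.tumor_radii)
        ref_phantom = config.make_phantom(ref_radius)
        if verbose:
            print(f"shared EM solve on r={ref_radius} mm phantom", flush=True)
        shared_fields = compute_unit_fields(ref_phantom, config, verbose=verbose)
    for r in config.tumor_radii:
        if verbose:
            print(f"tumor radius {r} mm ...", flush=True)
        res = plan_single_radius(
            config, r, fields=shared_fields, verbose=verbose
        )
        sweep.results.append(res)
    return sweep


def report(sweep: SweepResult, outdir) -> list[str]:
    """Write the sweep as CSV tables, transient curves, and dB SAR slice
    renders; returns the written paths."""
    import pathlib

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    rows = []
    for res in sweep.results:
        for n, (p, ph) in enumerate(
            zip(res.excitation.powers, res.excitation.phases_deg), start=1
        ):
            rows.append({
                "tumor_radius_mm": res.tumor_radius, "antenna": n,
                "power_W": p, "phase_deg": ph,
            })
    path = out / "optimal_excitations.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    written.append(str(path))

    summary = pd.DataFrame([
        {
            "tumor_radius_mm": r.tumor_radius,
            "sar_ratio": r.sar_ratio,
            "sar_vol_tumor_W_per_kg": r.sar_vol_tumor,
            "sar_vol_tumor_uniform_W_per_kg": r.sar_vol_tumor_uniform,
            "sar_max_tumor_W_per_kg": r.sar_max_tumor,
            "T_end_center_C": r.T_end_center,
            "T_end_tumor_max_C": r.T_end_tumor_max,
        }
        for r in sweep.results
    ])
    path = out / "sweep_summary.csv"
    summary.to_csv(path, index=False)
    written.append(str(path))

    for res in sweep.results:
        df = pd.DataFrame({
            "t_s": res.t, "T_center_C": res.T_center,
            "T_tumor_max_C": res.T_tumor_max,
        })
        path = out / f"transient_r{res.tumor_radius:g}mm.csv"
        df.to_csv(path, index=False)
        written.append(str(path))

        fig, ax = plt.subplots(figsize=(5, 4))
        im = ax.imshow(res.db_slice.T, origin="lower", vmin=-40, vmax=0,
                       cmap="jet")
        fig.colorbar(im, ax=ax, label="SAR (dB re max)")
        ax.set_title(f"tumor r = {res.tumor_radius:g} mm")
        path = out / f"sar_db_r{res.tumor_radius:g}mm.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(str(path))

    log = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(sweep.config).items()},
        "n_radii": len(sweep.results),
        "versions": _versions(),
    }
    path = out / "run_log.json"
    with open(path, "w") as fh:
        json.dump(log, fh, indent=1, sort_keys=True)
    written.append(str(path))
    return written


def _versions() -> dict:
    import numba
    import scipy

    from . import __version__

    return {
        "htplan": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "numba": numba.__version__,
    }
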