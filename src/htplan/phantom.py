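"""Synthetic voxel breast phantoms.

The generator emulates an MRI-derived heterogeneously dense breast model as
a hemispherical breast seated on a cylindrical pectoral-muscle slab: an
outer skin shell, a subcutaneous fat shell, and an interior in which
glandular tissue and interstitial breast fat are interleaved by seeded,
spatially correlated (lobulated) noise.  A spherical tumor of configurable
radius is embedded inside the glandular interior.  Composition classes
(PF, SFG, HD, ED) fix the target muscle/gland/fat volume split of the soft
tissue; the generator solves the slab thickness and the gland/breast-fat
noise threshold so the realized voxel fractions land on the targets.

Coordinate convention: right-handed, millimetres, the antenna-array center
is the physical origin, voxel cell centers lie on integer multiples of the
spacing (cell-centered grid), and the breast protrudes toward -x from a
chest wall at +x.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

from .tissues import TissueProperties, build_tissue_table

__all__ = [
    "VoxelPhantom",
    "GeometryError",
    "ResolutionError",
    "COMPOSITION_CLASSES",
    "LABELS",
    "generate_breast_phantom",
    "uniform_phantom",
    "composition_report",
    "save_phantom",
    "load_phantom",
]


class GeometryError(ValueError):
    """Requested geometry is inconsistent (e.g. tumor outside the gland)."""


class ResolutionError(ValueError):
    """Voxel spacing too coarse to resolve a requested feature."""


#: target (muscle, gland, fat) soft-tissue volume fractions per breast
#: composition class; fat pools subcutaneous fat and interstitial breast fat
COMPOSITION_CLASSES = {
    "PF": (0.10, 0.20, 0.70),
    "SFG": (0.20, 0.40, 0.40),
    "HD": (0.20, 0.60, 0.20),
    "ED": (0.20, 0.70, 0.10),
}

#: integer labels of the voxel grid (0 = exterior air)
LABELS = {
    "air": 0,
    "skin": 1,
    "fat": 2,
    "breast_fat": 3,
    "gland": 4,
    "muscle": 5,
    "tumor": 6,
}
_NAME_BY_LABEL = {v: k for k, v in LABELS.items()}


@dataclass
class VoxelPhantom:
    """Labeled voxel grid with physical metadata.

    ``labels[i, j, k]`` is the tissue label of the cell centered at
    ``origin + spacing * (i, j, k)`` (mm).  ``label_map`` maps nonzero
    labels to :class:`~htplan.tissues.TissueProperties`.
    """

    labels: np.ndarray
    spacing: float
    origin: np.ndarray
    label_map: dict[int, TissueProperties]
    tumor_center: tuple[float, float, float] | None = None
    tumor_radius: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.origin = np.asarray(self.origin, dtype=float)
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.label_map)
        if missing:
            raise ValueError(f"labels without tissue entry: {sorted(missing)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def voxel_centers(self, axis: int) -> np.ndarray:
        """Physical cell-center coordinates (mm) along one axis."""
        return self.origin[axis] + self.spacing * np.arange(self.labels.shape[axis])

    def index_of(self, point_mm) -> tuple[int, int, int]:
        """Index of the voxel whose cell contains the physical point."""
        idx = np.rint((np.asarray(point_mm, float) - self.origin) / self.spacing)
        idx = idx.astype(int)
        if np.any(idx < 0) or np.any(idx >= np.array(self.labels.shape)):
            raise GeometryError(f"point {point_mm} outside the phantom grid")
        return tuple(idx)

    def mask(self, *names: str) -> np.ndarray:
        """Boolean mask of the voxels carrying any of the named tissues."""
        m = np.zeros(self.labels.shape, dtype=bool)
        for n in names:
            m |= self.labels == LABELS[n]
        return m

    def property_grid(self, attr: str, default: float = 0.0) -> np.ndarray:
        """Per-voxel array of one tissue property (``default`` in air)."""
        out = np.full(self.labels.shape, default, dtype=float)
        for lab, props in self.label_map.items():
            val = getattr(props, attr)
            if val is None:
                continue
            out[self.labels == lab] = val
        return out


def _default_label_map() -> dict[int, TissueProperties]:
    table = build_tissue_table()
    return {lab: table[name] for name, lab in LABELS.items() if name != "air"}


def uniform_phantom(
    shape,
    spacing: float,
    tissue: TissueProperties,
    origin=None,
) -> VoxelPhantom:
    """Homogeneous single-tissue block (test and benchmark fixture)."""
    shape = tuple(int(s) for s in shape)
    labels = np.ones(shape, dtype=np.int16)
    if origin is None:
        origin = -spacing * (np.array(shape) - 1) / 2.0
    return VoxelPhantom(labels, spacing, np.asarray(origin, float), {1: tissue})


def generate_breast_phantom(
    spacing: float = 3.0,
    breast_radius: float = 70.0,
    skin_thickness: float = 2.0,
    fat_shell_thickness: float = 4.0,
    slab_radius: float = 72.0,
    tumor_radius: float = 12.0,
    tumor_center=(0.0, -12.0, 12.0),
    composition_class: str = "HD",
    seed: int = 0,
    noise_correlation_mm: float = 8.0,
    air_margin_cells: int = 2,
) -> VoxelPhantom:
    """Generate a layered hemispherical breast phantom with embedded tumor.

    The breast hemisphere (radius ``breast_radius``) is centered on the
    chest-wall plane at ``x = breast_radius / 2`` so that the array center
    (the origin) falls inside the glandular interior.  The muscle slab
    thickness is solved so the soft-tissue muscle fraction hits the
    composition-class target; the gland/breast-fat split of the interior is
    thresholded seeded correlated noise, with the threshold chosen to hit
    the gland target exactly at voxel granularity.

    Raises
    ------
    ResolutionError
        if the spacing cannot resolve the skin shell.
    GeometryError
        if the tumor sphere does not fit inside the glandular interior.
    """
    if composition_class not in COMPOSITION_CLASSES:
        raise ValueError(f"unknown composition class {composition_class!r}")
    if skin_thickness <= 0 or spacing <= 0:
        raise ValueError("spacing and skin_thickness must be positive")
    if skin_thickness < 0.5 * spacing:
        raise ResolutionError(
            f"spacing {spacing} mm too coarse for a {skin_thickness} mm skin shell"
        )
    m_t, g_t, _f_t = COMPOSITION_CLASSES[composition_class]

    t_skin = max(skin_thickness, spacing)  # closed shell needs >= 1 voxel
    r_fat = breast_radius - t_skin                       # outer radius of fat shell
    r_int = r_fat - fat_shell_thickness                  # outer radius of interior
    x_wall = breast_radius / 2.0                         # chest-wall plane
    center = np.array([x_wall, 0.0, 0.0])

    # continuum volumes (half-shells cut by the chest wall through center)
    v_int = 0.5 * 4.0 / 3.0 * np.pi * r_int**3
    v_fat = 0.5 * 4.0 / 3.0 * np.pi * (r_fat**3 - r_int**3)
    # slab thickness solving muscle target: m = m_t/(1-m_t) * (v_fat + v_int)
    v_slab = m_t / (1.0 - m_t) * (v_fat + v_int)
    slab_thickness = v_slab / (np.pi * slab_radius**2)

    # grid bounds (cell centers on integer multiples of spacing)
    pad = air_margin_cells * spacing
    lo = np.array([x_wall - breast_radius - pad, -slab_radius - pad, -slab_radius - pad])
    hi = np.array([x_wall + slab_thickness, slab_radius + pad, slab_radius + pad])
    i_lo = np.floor(lo / spacing).astype(int)
    i_hi = np.ceil(hi / spacing).astype(int)
    # grid ends flush with the slab back: the +x boundary is the chest side
    i_hi[0] = int(np.ceil((x_wall + slab_thickness) / spacing - 0.5 - 1e-9))
    shape = tuple(i_hi - i_lo + 1)
    origin = i_lo * spacing
    xs = origin[0] + spacing * np.arange(shape[0])
    ys = origin[1] + spacing * np.arange(shape[1])
    zs = origin[2] + spacing * np.arange(shape[2])
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")

    d = np.sqrt((X - center[0]) ** 2 + Y**2 + Z**2)
    in_breast = (d < breast_radius) & (X < x_wall)
    labels = np.zeros(shape, dtype=np.int16)
    labels[in_breast & (d >= r_fat)] = LABELS["skin"]
    labels[in_breast & (d < r_fat) & (d >= r_int)] = LABELS["fat"]
    interior = in_breast & (d < r_int)

    # slab fills from the chest wall to the grid's +x boundary
    slab = (X >= x_wall) & (Y**2 + Z**2 < slab_radius**2)
    labels[slab & ~in_breast] = LABELS["muscle"]

    # close the surface: any soft-tissue voxel facing air becomes skin,
    # except on the +x (chest continues beyond the grid) boundary plane
    air = labels == 0
    face_air = np.zeros(shape, dtype=bool)
    for ax in range(3):
        for sh in (1, -1):
            nb = np.roll(air, sh, axis=ax)
            edge_in = 0 if sh == 1 else -1
            idx = [slice(None)] * 3
            idx[ax] = edge_in
            nb[tuple(idx)] = ax != 0 or sh != -1  # +x face treated as tissue
            face_air |= nb
    coat = face_air & (labels != 0) & ~interior
    labels[coat] = LABELS["skin"]

    # gland / breast-fat split of the interior by correlated-noise quantile
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(shape)
    noise = ndimage.gaussian_filter(noise, sigma=noise_correlation_mm / spacing)
    n_int = int(interior.sum())
    if n_int == 0:
        raise GeometryError("empty glandular interior; enlarge breast_radius")
    n_soft = n_int + int((labels == LABELS["fat"]).sum()) + int(
        (labels == LABELS["muscle"]).sum()
    )
    n_gland = int(round(g_t * n_soft))
    if n_gland > n_int:
        warnings.warn(
            f"{composition_class}: gland target needs {n_gland} voxels, interior has "
            f"{n_int}; filling the whole interior with gland",
            stacklevel=2,
        )
        n_gland = n_int
    vals = noise[interior]
    order = np.argsort(vals, kind="stable")
    gland_sel = np.zeros(n_int, dtype=bool)
    gland_sel[order[:n_gland]] = True  # lowest-noise pockets become gland lobes
    sub = labels[interior]
    sub[:] = LABELS["breast_fat"]
    sub[gland_sel] = LABELS["gland"]
    labels[interior] = sub

    # tumor sphere (center-of-voxel-inside-sphere rule), overwriting interior
    tumor_center = tuple(float(c) for c in tumor_center)
    if tumor_radius > 0:
        tc = np.asarray(tumor_center)
        dt = np.sqrt((X - tc[0]) ** 2 + (Y - tc[1]) ** 2 + (Z - tc[2]) ** 2)
        tum = dt < tumor_radius
        if not np.all(interior[tum]):
            raise GeometryError(
                "tumor sphere extends outside the glandular interior"
            )
        labels[tum] = LABELS["tumor"]

    return VoxelPhantom(
        labels,
        spacing,
        origin,
        _default_label_map(),
        tumor_center=tumor_center,
        tumor_radius=float(tumor_radius),
        meta={
            "composition_class": composition_class,
            "seed": seed,
            "breast_radius": breast_radius,
            "skin_thickness": skin_thickness,
            "fat_shell_thickness": fat_shell_thickness,
            "slab_radius": slab_radius,
            "slab_thickness": float(slab_thickness),
            "chest_wall_x": float(x_wall),
            "noise_correlation_mm": noise_correlation_mm,
        },
    )


def composition_report(phantom: VoxelPhantom) -> dict[str, float]:
    """Per-tissue volume fractions over the non-air voxels (sum to 1)."""
    nz = phantom.labels[phantom.labels != 0]
    if nz.size == 0:
        raise ValueError("empty phantom: no tissue voxels")
    out: dict[str, float] = {}
    labs, counts = np.unique(nz, return_counts=True)
    for lab, c in zip(labs, counts):
        out[phantom.label_map[int(lab)].name] = c / nz.size
    return out


def soft_tissue_fractions(phantom: VoxelPhantom) -> dict[str, float]:
    """Muscle/gland/fat split of the soft tissue (skin and tumor excluded);
    fat pools subcutaneous fat and interstitial breast fat, tumor counts as
    gland volume it displaced."""
    lab = phantom.labels
    m = int(np.sum(lab == LABELS["muscle"]))
    g = int(np.sum((lab == LABELS["gland"]) | (lab == LABELS["tumor"])))
    f = int(np.sum((lab == LABELS["fat"]) | (lab == LABELS["breast_fat"])))
    tot = m + g + f
    return {"muscle": m / tot, "gland": g / tot, "fat": f / tot}


# ---------------------------------------------------------------- NIfTI I/O

def save_phantom(phantom: VoxelPhantom, nifti_path, sidecar_path=None) -> None:
    """Write the label volume as NIfTI-1 plus a JSON metadata sidecar."""
    affine = np.diag([phantom.spacing] * 3 + [1.0])
    affine[:3, 3] = phantom.origin
    nib.save(nib.Nifti1Image(phantom.labels.astype(np.int16), affine), str(nifti_path))
    sidecar_path = (
        str(nifti_path).replace(".nii.gz", "").replace(".nii", "") + ".json"
        if sidecar_path is None
        else sidecar_path
    )
    tissues = {}
    for lab, p in phantom.label_map.items():
        tissues[str(lab)] = {
            "name": p.name, "eps_r": p.eps_r, "sigma": p.sigma, "rho": p.rho,
            "C": p.C, "k": p.k, "HTR": p.HTR, "HGR": p.HGR,
        }
    with open(sidecar_path, "w") as fh:
        json.dump(
            {
                "spacing_mm": phantom.spacing,
                "origin_mm": list(phantom.origin),
                "tumor_center_mm": phantom.tumor_center,
                "tumor_radius_mm": phantom.tumor_radius,
                "label_map": tissues,
                "meta": phantom.meta,
            },
            fh,
            indent=1,
        )


def load_phantom(nifti_path, sidecar_path=None) -> VoxelPhantom:
    img = nib.load(str(nifti_path))
    labels = np.asarray(img.dataobj).astype(np.int16)
    sidecar_path = (
        str(nifti_path).replace(".nii.gz", "").replace(".nii", "") + ".json"
        if sidecar_path is None
        else sidecar_path
    )
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    label_map = {
        int(lab): TissueProperties(**props)
        for lab, props in meta["label_map"].items()
    }
    tc = meta.get("tumor_center_mm")
    return VoxelPhantom(
        labels,
        float(meta["spacing_mm"]),
        np.asarray(meta["origin_mm"], float),
        label_map,
        tumor_center=tuple(tc) if tc is not None else None,
        tumor_radius=float(meta.get("tumor_radius_mm", 0.0)),
        meta=meta.get("meta", {}),
    )
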