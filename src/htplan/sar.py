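"""Specific absorption rate: pointwise, superposed, and quadratic forms.

The SAR of the combined field of an N-antenna array is a Hermitian
quadratic form in the complex excitation vector A (A_n = √P_n e^{jϕ_n}):
SAR(r) = A^H K(r) A with K_mn(r) = [σ(r)/(2ρ(r))] Σ_i E*_{m,i}(r) E_{n,i}(r),
so region-averaged SAR reduces to an N×N Hermitian matrix H — the volume
average of K — that no longer depends on the excitation.  The classical
amplitude/phase parametrization (β′_mn, Ω′_mn) is the polar form of H's
entries; computing H directly as a complex average avoids arctan-quadrant
pitfalls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fdtd import ComplexFieldVolume, extract_on_phantom

__all__ = [
    "ExcitationVector",
    "SarQuadraticForm",
    "pointwise_sar",
    "combine_fields",
    "build_quadratic_form",
    "sar_vol",
    "sar_map",
]


@dataclass(frozen=True)
class ExcitationVector:
    """Per-antenna powers (W) and phases (deg, in [-180, 180]).

    The implied complex amplitude is A_n = √(P_n / 1 W) · e^{jϕ_n}; the
    last antenna is the phase reference (gauge ϕ_N = 0 by convention, not
    enforced here).
    """

    powers: tuple[float, ...]
    phases_deg: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.powers) != len(self.phases_deg):
            raise ValueError("powers and phases length mismatch")
        if any(p < 0 for p in self.powers):
            raise ValueError("negative power")
        if any(abs(ph) > 180.0 + 1e-9 for ph in self.phases_deg):
            raise ValueError("phase outside [-180, 180] deg")

    @property
    def n_antennas(self) -> int:
        return len(self.powers)

    @property
    def amplitudes(self) -> np.ndarray:
        """Complex A_n = √P_n e^{jϕ_n} (dimensionless, P in W)."""
        return np.sqrt(np.asarray(self.powers)) * np.exp(
            1j * np.deg2rad(np.asarray(self.phases_deg))
        )

    @property
    def total_power(self) -> float:
        return float(np.sum(self.powers))

    @classmethod
    def from_amplitudes(cls, A, reference_last: bool = True) -> "ExcitationVector":
        """Build from complex amplitudes; optionally gauge the last
        antenna's phase to zero (a common phase shift changes no SAR)."""
        A = np.asarray(A, dtype=complex)
        if reference_last and A[-1] != 0:
            A = A * np.exp(-1j * np.angle(A[-1]))
        ph = np.rad2deg(np.angle(A))
        if reference_last:
            ph[-1] = 0.0  # exact gauge, not within rounding
        ph[np.abs(ph + 180.0) < 1e-12] = 180.0  # wrap -180 -> 180 consistently
        return cls(tuple(np.abs(A) ** 2), tuple(ph))

    @classmethod
    def uniform(cls, n: int, power_per_antenna: float = 1.0) -> "ExcitationVector":
        return cls((power_per_antenna,) * n, (0.0,) * n)


def pointwise_sar(E_total: np.ndarray, sigma, rho) -> np.ndarray:
    """SAR = σ|E|²/(2ρ) (W/kg) for complex E (..., with leading 3-axis or
    a plain 3-vector); σ, ρ scalars or arrays broadcastable to the result."""
    E = np.asarray(E_total)
    if E.shape[0] != 3:
        raise ValueError("E_total must have the 3 components on axis 0")
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("rho must be positive")
    mag2 = np.sum(np.abs(E) ** 2, axis=0)
    return np.asarray(sigma) * mag2 / (2.0 * rho)


def _check_compatible(unit_fields: list[ComplexFieldVolume]) -> None:
    f0 = unit_fields[0]
    for f in unit_fields[1:]:
        if f.E.shape != f0.E.shape or not np.allclose(f.origin, f0.origin):
            raise ValueError("unit fields must share one grid")
    for f in unit_fields:
        if not np.isclose(f.accepted_power_norm, 1.0):
            raise ValueError(
                f"antenna {f.antenna_index}: field not normalized to 1 W"
            )


def combine_fields(
    unit_fields: list[ComplexFieldVolume], excitation: ExcitationVector
) -> ComplexFieldVolume:
    """Superpose unit fields: E(r) = Σ_n A_n E_n(r), componentwise."""
    _check_compatible(unit_fields)
    if excitation.n_antennas != len(unit_fields):
        raise ValueError("excitation size does not match number of antennas")
    A = excitation.amplitudes
    E = np.zeros_like(unit_fields[0].E)
    for a, f in zip(A, unit_fields):
        E = E + a * f.E
    f0 = unit_fields[0]
    return ComplexFieldVolume(
        E=E, spacing=f0.spacing, origin=f0.origin, antenna_index=-1,
        accepted_power_norm=np.nan,
        port={"combined": True, "total_power_W": excitation.total_power},
    )


@dataclass
class SarQuadraticForm:
    """Region-averaged SAR as the Hermitian form A^H H A.

    ``H`` is N×N Hermitian positive semidefinite; ``beta`` (|H_mn|) and
    ``omega_deg`` (arg H_mn) expose the field-convention polar
    parametrization.  ``voxel_count`` is the number of cells averaged.
    """

    H: np.ndarray
    voxel_count: int
    region_id: str = ""

    def __post_init__(self) -> None:
        H = np.asarray(self.H)
        if H.ndim != 2 or H.shape[0] != H.shape[1]:
            raise ValueError("H must be square")
        if not np.allclose(H, H.conj().T, atol=1e-12 * max(1.0, np.abs(H).max())):
            raise ValueError("H must be Hermitian")
        self.H = 0.5 * (H + H.conj().T)

    @property
    def n_antennas(self) -> int:
        return self.H.shape[0]

    @property
    def beta(self) -> np.ndarray:
        return np.abs(self.H)

    @property
    def omega_deg(self) -> np.ndarray:
        return np.rad2deg(np.angle(self.H))


def build_quadratic_form(
    unit_fields: list[ComplexFieldVolume],
    region_mask: np.ndarray,
    sigma: np.ndarray,
    rho: np.ndarray,
    region_id: str = "",
    field_arrays: np.ndarray | None = None,
) -> SarQuadraticForm:
    """Average the per-voxel SAR kernel over a region.

    H_mn = (1/M) Σ_{l∈region} [σ_l/(2ρ_l)] Σ_i E*_{m,i}(r_l) E_{n,i}(r_l)

    ``region_mask``, ``sigma`` and ``rho`` are on the same grid as the unit
    fields (or pass ``field_arrays`` with shape (N, 3, M) for pre-extracted
    voxel lists).
    """
    if field_arrays is None:
        _check_compatible(unit_fields)
        mask = np.asarray(region_mask, bool)
        if not mask.any():
            raise ValueError(f"empty region {region_id!r}")
        F = np.stack([f.E[:, mask] for f in unit_fields])  # (N, 3, M)
        w = np.asarray(sigma)[mask] / (2.0 * np.asarray(rho)[mask])
    else:
        F = np.asarray(field_arrays)
        if F.shape[-1] == 0:
            raise ValueError(f"empty region {region_id!r}")
        w = np.asarray(sigma) / (2.0 * np.asarray(rho))
    M = F.shape[-1]
    # H_mn = mean_l w_l sum_i conj(F_m,i,l) F_n,i,l
    Fw = F * w  # broadcast over voxels
    H = np.einsum("mil,nil->mn", F.conj(), Fw) / M
    H = 0.5 * (H + H.conj().T)
    return SarQuadraticForm(H=H, voxel_count=M, region_id=region_id)


def sar_vol(form: SarQuadraticForm, excitation: ExcitationVector) -> float:
    """Region-mean SAR (W/kg) of an excitation: Re(A^H H A)."""
    A = excitation.amplitudes
    if A.size != form.n_antennas:
        raise ValueError("excitation size does not match the form")
    val = float(np.real(A.conj() @ form.H @ A))
    if val < -1e-9 * max(1.0, float(np.abs(form.H).max())):
        raise RuntimeError(f"negative region SAR {val}: inconsistent form")
    return max(val, 0.0)


def sar_map(
    unit_fields: list[ComplexFieldVolume],
    excitation: ExcitationVector,
    phantom,
) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise SAR (W/kg) on the phantom grid and the dB map
    10·log10(SAR/SAR_max); air voxels are NaN in the dB map."""
    combined = combine_fields(unit_fields, excitation)
    E = extract_on_phantom(combined, phantom)
    sigma = phantom.property_grid("sigma")
    rho = phantom.property_grid("rho", default=1.0)
    sar = pointwise_sar(E, sigma, rho)
    tissue = phantom.labels != 0
    sar[~tissue] = 0.0
    smax = sar.max()
    if smax <= 0:
        raise ValueError("all-zero SAR: dB map undefined")
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(sar / smax)
    db[~tissue] = np.nan
    return sar, db
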