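"""Dipole antenna specifications, ring-array placement, and the analytic
thin-wire field oracle.

The array is a ring of N center-fed dipoles in the x = 0 plane; every
dipole's arms run parallel to the x axis, so the feed gap sits on the ring
and the wires pierce the ring plane perpendicular to it.  The analytic
oracle evaluates the closed-form field of a center-fed thin-wire dipole
with an assumed sinusoidal current distribution in a homogeneous (possibly
lossy) medium — the classical three-ray expression — and serves as an
independent check of the FDTD solver.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

C0 = 299792458.0
EPS0 = 8.8541878128e-12
MU0 = 4e-7 * np.pi
ETA0 = np.sqrt(MU0 / EPS0)

__all__ = [
    "DipoleSpec",
    "ArrayGeometry",
    "place_array",
    "analytic_dipole_field",
    "complex_wavenumber",
]


@dataclass(frozen=True)
class DipoleSpec:
    """Geometry and drive of one center-fed dipole.

    Lengths in mm.  ``arm_length`` is one arm of the shortened half-wave
    design (arm ≈ k_s·λ/4 with shortening factor k_s = 0.67 at 1 GHz).
    ``axis``
    is the wire direction (unit vector).  ``amplitude`` is the open-circuit
    source voltage (V) behind ``source_resistance`` ohms.
    """

    feed_position: tuple[float, float, float]
    arm_length: float = 50.0
    wire_radius: float = 1.0
    gap: float = 1.0
    axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    source_resistance: float = 50.0
    frequency: float = 1.0e9
    amplitude: float = 1.0
    phase_deg: float = 0.0

    @property
    def half_length(self) -> float:
        """Feed-to-tip length h = arm + gap/2 (mm)."""
        return self.arm_length + self.gap / 2.0

    @property
    def wavelength(self) -> float:
        """Free-space wavelength (mm)."""
        return C0 / self.frequency * 1e3

    @property
    def shortening_factor(self) -> float:
        """Arm length relative to the quarter-wave arm of a resonant dipole."""
        return self.arm_length / (self.wavelength / 4.0)


@dataclass(frozen=True)
class ArrayGeometry:
    """Ring of dipoles in the x = 0 plane, axes along x."""

    n_antennas: int = 8
    ring_radius: float = 100.0
    start_angle_deg: float = 0.0

    @property
    def angular_positions_deg(self) -> np.ndarray:
        return self.start_angle_deg + 360.0 / self.n_antennas * np.arange(
            self.n_antennas
        )


def place_array(
    geometry: ArrayGeometry,
    dipole: DipoleSpec | None = None,
    phantom=None,
) -> list[DipoleSpec]:
    """Place N dipoles evenly on the ring; feed k at angle θ_k from +y
    toward +z: (0, R cosθ_k, R sinθ_k).

    If a phantom is given, checks that no wire (extending ±(gap/2 +
    arm_length) along x) touches a tissue voxel.
    """
    proto = dipole if dipole is not None else DipoleSpec((0.0, 0.0, 0.0))
    specs = []
    for theta in np.deg2rad(geometry.angular_positions_deg):
        feed = (0.0, geometry.ring_radius * np.cos(theta), geometry.ring_radius * np.sin(theta))
        specs.append(replace(proto, feed_position=feed, axis=(1.0, 0.0, 0.0)))
    if phantom is not None:
        half = proto.half_length + proto.wire_radius
        for s in specs:
            f = np.asarray(s.feed_position)
            for xo in np.linspace(-half, half, 64):
                p = f + xo * np.asarray(s.axis)
                try:
                    idx = phantom.index_of(p)
                except Exception:
                    continue
                if phantom.labels[idx] != 0:
                    raise ValueError(
                        f"dipole at feed {s.feed_position} intersects tissue"
                    )
    return specs


def complex_wavenumber(eps_r: float, sigma: float, frequency: float) -> complex:
    """k = ω√(μ0 ε_c) with ε_c = ε0 εr − jσ/ω (engineering e^{+jωt})."""
    omega = 2 * np.pi * frequency
    eps_c = EPS0 * eps_r - 1j * sigma / omega
    k = omega * np.sqrt(MU0 * eps_c)
    # branch with decaying wave: Re k > 0, Im k < 0
    if k.real < 0:
        k = -k
    return k


def analytic_dipole_field(
    dipole: DipoleSpec,
    points_mm: np.ndarray,
    eps_r: float = 1.0,
    sigma: float = 0.0,
    feed_current: complex = 1.0,
    half_length_mm: float | None = None,
) -> np.ndarray:
    """Closed-form E field (V/m) of a thin-wire dipole with sinusoidal
    current in a homogeneous medium.

    Parameters
    ----------
    points_mm : (M, 3) field points in mm.
    feed_current : complex current phasor at the feed (A); the standing-wave
        maximum is ``feed_current / sin(kh)``.
    half_length_mm : override of the feed-to-tip length h (mm), e.g. to
        match a grid-snapped wire.

    Returns
    -------
    (M, 3) complex E vectors.  Raises if a point lies within the wire
    radius of the antenna axis segment.
    """
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    axis = np.asarray(dipole.axis, float)
    axis = axis / np.linalg.norm(axis)
    feed = np.asarray(dipole.feed_position, float)
    h = (half_length_mm if half_length_mm is not None else dipole.half_length) * 1e-3

    rel = (pts - feed) * 1e-3
    z = rel @ axis                      # axial coordinate (m)
    rho_vec = rel - np.outer(z, axis)
    rho = np.linalg.norm(rho_vec, axis=1)
    on_wire = (rho < dipole.wire_radius * 1e-3) & (np.abs(z) <= h + 1e-12)
    if np.any(on_wire):
        raise ValueError("field point inside the wire")

    k = complex_wavenumber(eps_r, sigma, dipole.frequency)
    omega = 2 * np.pi * dipole.frequency
    eps_c = EPS0 * eps_r - 1j * sigma / omega
    eta = np.sqrt(MU0 / eps_c)
    if eta.real < 0:
        eta = -eta
    i_max = feed_current / np.sin(k * h)

    r1 = np.sqrt(rho**2 + (z - h) ** 2)
    r2 = np.sqrt(rho**2 + (z + h) ** 2)
    r0 = np.sqrt(rho**2 + z**2)
    e1 = np.exp(-1j * k * r1) / r1
    e2 = np.exp(-1j * k * r2) / r2
    e0 = np.exp(-1j * k * r0) / r0
    ckh = 2 * np.cos(k * h)

    ez = -1j * eta * i_max / (4 * np.pi) * (e1 + e2 - ckh * e0)
    with np.errstate(divide="ignore", invalid="ignore"):
        erho = (
            1j
            * eta
            * i_max
            / (4 * np.pi * rho)
            * ((z - h) * e1 + (z + h) * e2 - ckh * z * e0)
        )
    erho = np.where(rho < 1e-9, 0.0, erho)

    rho_hat = np.zeros_like(rho_vec)
    ok = rho > 1e-12
    rho_hat[ok] = rho_vec[ok] / rho[ok, None]
    E = ez[:, None] * axis[None, :] + erho[:, None] * rho_hat
    return E
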