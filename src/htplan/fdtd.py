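"""Time-harmonic FDTD solver for dipole fields in voxel phantoms.

A standard Yee-grid finite-difference time-domain scheme with convolutional
PML (CPML) absorbing boundaries, one-cell PEC thin wires for the dipole
arms, and a one-cell resistive voltage source (edge port).  A continuous-
wave run with a raised-cosine ramp is demodulated at the drive frequency
over integer-period windows until the field phasor settles; the result is
the steady-state complex E field, normalized so the power accepted at the
port is 1 W.

Conventions: engineering time dependence e^{+jωt} (phasor Ê with
E(t) = Re[Ê e^{jωt}]); cell-centered grid whose cell centers lie on
integer multiples of the spacing in the global (array-centered) frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import h5py
import numpy as np
from numba import njit

from .dipole import C0, EPS0, ETA0, MU0, DipoleSpec

__all__ = [
    "SolverConfig",
    "ComplexFieldVolume",
    "ConvergenceError",
    "fdtd_unit_field",
    "normalize_to_power",
    "port_sweep",
    "s11_db",
    "extract_on_phantom",
    "save_fields_h5",
    "load_fields_h5",
]


class ConvergenceError(RuntimeError):
    """Steady-state phasor did not settle within the allowed run time."""


@dataclass
class SolverConfig:
    """FDTD solver settings (lengths in mm unless noted)."""

    spacing: float = 3.0
    courant: float = 0.99           # fraction of the 3-D CFL limit
    pml_cells: int = 8
    pml_order: int = 3
    pml_sigma_factor: float = 0.8   # sigma_max = f*(m+1)/(eta0*dx)
    pml_alpha: float = 0.05
    pad_cells: int | tuple = 3      # gap between geometry and PML (per axis ok)
    ramp_periods: float = 6.0
    demod_periods: int = 4          # demodulation window length (periods)
    max_periods: int = 60
    convergence_tol: float = 1e-3   # relative phasor change between windows
    min_cells_per_wavelength: float = 10.0


@dataclass
class ComplexFieldVolume:
    """Cell-centered complex E field (V/m) of one antenna.

    ``E`` has shape (3, nx, ny, nz); the voxel (i, j, k) center sits at
    ``origin + spacing*(i, j, k)`` mm.  ``accepted_power_norm`` is the port
    power the field is normalized to (1.0 W after normalization).
    """

    E: np.ndarray
    spacing: float
    origin: np.ndarray
    antenna_index: int = 0
    accepted_power_norm: float = np.nan
    port: dict = dfield(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.E.shape[1:]

    def sample(self, point_mm) -> np.ndarray:
        """Complex E 3-vector at the voxel containing a physical point."""
        idx = np.rint((np.asarray(point_mm, float) - self.origin) / self.spacing)
        i, j, k = idx.astype(int)
        return self.E[:, i, j, k]


# ------------------------------------------------------------- Yee kernels

@njit(cache=True, fastmath=True)
def _step_E(Ex, Ey, Ez, Hx, Hy, Hz,
            CaX, CbX, CaY, CbY, CaZ, CbZ,
            pExy, pExz, pEyz, pEyx, pEzx, pEzy,
            bxn, cxn, byn, cyn, bzn, czn, inv_d):
    # psi (CPML memory) terms are touched only where their c profile is
    # nonzero, i.e. inside the PML slabs
    nx = Ex.shape[0]
    ny = Ey.shape[1]
    nz = Ez.shape[2]
    for i in range(nx):
        for j in range(1, ny):
            cy = cyn[j]
            for k in range(1, nz):
                dhzy = (Hz[i, j, k] - Hz[i, j - 1, k]) * inv_d
                dhyz = (Hy[i, j, k] - Hy[i, j, k - 1]) * inv_d
                curl = dhzy - dhyz
                if cy != 0.0:
                    pExy[i, j, k] = byn[j] * pExy[i, j, k] + cy * dhzy
                    curl += pExy[i, j, k]
                if czn[k] != 0.0:
                    pExz[i, j, k] = bzn[k] * pExz[i, j, k] + czn[k] * dhyz
                    curl -= pExz[i, j, k]
                Ex[i, j, k] = CaX[i, j, k] * Ex[i, j, k] + CbX[i, j, k] * curl
    for i in range(1, nx):
        cx = cxn[i]
        for j in range(ny):
            for k in range(1, nz):
                dhxz = (Hx[i, j, k] - Hx[i, j, k - 1]) * inv_d
                dhzx = (Hz[i, j, k] - Hz[i - 1, j, k]) * inv_d
                curl = dhxz - dhzx
                if czn[k] != 0.0:
                    pEyz[i, j, k] = bzn[k] * pEyz[i, j, k] + czn[k] * dhxz
                    curl += pEyz[i, j, k]
                if cx != 0.0:
                    pEyx[i, j, k] = bxn[i] * pEyx[i, j, k] + cx * dhzx
                    curl -= pEyx[i, j, k]
                Ey[i, j, k] = CaY[i, j, k] * Ey[i, j, k] + CbY[i, j, k] * curl
    for i in range(1, nx):
        cx = cxn[i]
        for j in range(1, ny):
            cy = cyn[j]
            for k in range(nz):
                dhyx = (Hy[i, j, k] - Hy[i - 1, j, k]) * inv_d
                dhxy = (Hx[i, j, k] - Hx[i, j - 1, k]) * inv_d
                curl = dhyx - dhxy
                if cx != 0.0:
                    pEzx[i, j, k] = bxn[i] * pEzx[i, j, k] + cx * dhyx
                    curl += pEzx[i, j, k]
                if cy != 0.0:
                    pEzy[i, j, k] = byn[j] * pEzy[i, j, k] + cy * dhxy
                    curl -= pEzy[i, j, k]
                Ez[i, j, k] = CaZ[i, j, k] * Ez[i, j, k] + CbZ[i, j, k] * curl


@njit(cache=True, fastmath=True)
def _step_H(Ex, Ey, Ez, Hx, Hy, Hz,
            pHxy, pHxz, pHyz, pHyx, pHzx, pHzy,
            bxc, cxc, byc, cyc, bzc, czc, inv_d, dtmu):
    nx = Ex.shape[0]
    ny = Ey.shape[1]
    nz = Ez.shape[2]
    for i in range(nx + 1):
        for j in range(ny):
            cy = cyc[j]
            for k in range(nz):
                dezy = (Ez[i, j + 1, k] - Ez[i, j, k]) * inv_d
                deyz = (Ey[i, j, k + 1] - Ey[i, j, k]) * inv_d
                curl = dezy - deyz
                if cy != 0.0:
                    pHxy[i, j, k] = byc[j] * pHxy[i, j, k] + cy * dezy
                    curl += pHxy[i, j, k]
                if czc[k] != 0.0:
                    pHxz[i, j, k] = bzc[k] * pHxz[i, j, k] + czc[k] * deyz
                    curl -= pHxz[i, j, k]
                Hx[i, j, k] -= dtmu * curl
    for i in range(nx):
        cx = cxc[i]
        for j in range(ny + 1):
            for k in range(nz):
                dexz = (Ex[i, j, k + 1] - Ex[i, j, k]) * inv_d
                dezx = (Ez[i + 1, j, k] - Ez[i, j, k]) * inv_d
                curl = dexz - dezx
                if czc[k] != 0.0:
                    pHyz[i, j, k] = bzc[k] * pHyz[i, j, k] + czc[k] * dexz
                    curl += pHyz[i, j, k]
                if cx != 0.0:
                    pHyx[i, j, k] = bxc[i] * pHyx[i, j, k] + cx * dezx
                    curl -= pHyx[i, j, k]
                Hy[i, j, k] -= dtmu * curl
    for i in range(nx):
        cx = cxc[i]
        for j in range(ny):
            cy = cyc[j]
            for k in range(nz + 1):
                deyx = (Ey[i + 1, j, k] - Ey[i, j, k]) * inv_d
                dexy = (Ex[i, j + 1, k] - Ex[i, j, k]) * inv_d
                curl = deyx - dexy
                if cx != 0.0:
                    pHzx[i, j, k] = bxc[i] * pHzx[i, j, k] + cx * deyx
                    curl += pHzx[i, j, k]
                if cy != 0.0:
                    pHzy[i, j, k] = byc[j] * pHzy[i, j, k] + cy * dexy
                    curl -= pHzy[i, j, k]
                Hz[i, j, k] -= dtmu * curl


@njit(cache=True, fastmath=True)
def _accumulate(Sc, Ss, F, c, s):
    f = F.ravel()
    a = Sc.ravel()
    b = Ss.ravel()
    for n in range(f.size):
        a[n] += f[n] * c
        b[n] += f[n] * s


def _cpml_profiles(n_cells: int, npml: int, dx: float, dt: float,
                   order: int, sig_factor: float, alpha: float):
    """CPML b/c coefficient vectors at node (n+1) and center (n) positions."""
    sig_max = sig_factor * (order + 1) / (ETA0 * dx)

    def coeffs(pos):  # pos in cell units from the low boundary
        d_lo = npml - pos
        d_hi = pos - (n_cells - npml)
        d = max(d_lo, d_hi, 0.0) / npml
        sig = sig_max * d**order
        if sig == 0.0 and d <= 0.0:
            return 1.0, 0.0
        b = np.exp(-(sig + alpha) * dt / EPS0)
        c = sig * (b - 1.0) / (sig + alpha)
        return b, c

    bn = np.empty(n_cells + 1)
    cn = np.empty(n_cells + 1)
    for j in range(n_cells + 1):
        bn[j], cn[j] = coeffs(float(j))
    bc = np.empty(n_cells)
    cc = np.empty(n_cells)
    for j in range(n_cells):
        bc[j], cc[j] = coeffs(j + 0.5)
    return bn, cn, bc, cc


# ------------------------------------------------------------ grid set-up

class _Domain:
    """Shared Yee domain: material coefficient arrays + wire/port indexing."""

    def __init__(self, phantom, dipoles: list[DipoleSpec], config: SolverConfig,
                 background=(1.0, 0.0)):
        self.config = config
        d = config.spacing
        self.dx = d * 1e-3
        self.dt = config.courant * self.dx / (C0 * np.sqrt(3.0))
        # snap dt so one source period is an integer number of steps:
        # demodulation windows then cover whole periods exactly
        period = 1.0 / dipoles[0].frequency
        self.dt = period / int(np.ceil(period / self.dt))

        # geometry extent (cell-center index bounds on the global lattice)
        pts = []
        if phantom is not None:
            if abs(phantom.spacing - d) > 1e-9:
                raise ValueError("phantom spacing must match solver spacing")
            pts.append(phantom.origin)
            pts.append(phantom.origin + d * (np.array(phantom.shape) - 1))
        for s in dipoles:
            f = np.asarray(s.feed_position)
            half = s.half_length
            pts.append(f - half * np.asarray(s.axis))
            pts.append(f + half * np.asarray(s.axis))
        pts = np.array(pts)
        pad = np.broadcast_to(np.asarray(config.pad_cells, int), (3,))
        halo = pad + config.pml_cells
        i_lo = np.floor(pts.min(axis=0) / d).astype(int) - halo
        i_hi = np.ceil(pts.max(axis=0) / d).astype(int) + halo
        self.i_lo = i_lo
        self.shape = tuple(i_hi - i_lo + 1)
        self.origin = i_lo * d  # center of cell (0,0,0), mm

        nx, ny, nz = self.shape
        eps = np.full(self.shape, background[0])
        sig = np.full(self.shape, background[1])
        if phantom is not None:
            off = np.rint((phantom.origin - self.origin) / d).astype(int)
            sl = tuple(slice(o, o + s) for o, s in zip(off, phantom.shape))
            eps[sl] = np.maximum(phantom.property_grid("eps_r", background[0]), 1.0)
            sig[sl] = phantom.property_grid("sigma", background[1])
            lam_min = C0 / dipoles[0].frequency / np.sqrt(eps.max()) * 1e3
            if lam_min / d < config.min_cells_per_wavelength:
                raise ValueError(
                    f"spacing {d} mm gives {lam_min / d:.1f} cells per wavelength "
                    f"in the densest tissue (need {config.min_cells_per_wavelength})"
                )
        self._build_coeffs(eps, sig)
        self._build_pml()

    def _edge_avg(self, vol, comp):
        """Average a cell property onto the 4 cells adjacent to each edge."""
        nx, ny, nz = self.shape
        if comp == 0:
            out = np.zeros((nx, ny + 1, nz + 1))
            acc = np.zeros_like(out)
            for dj in (0, 1):
                for dk in (0, 1):
                    out[:, dj:ny + dj, dk:nz + dk] += vol
                    acc[:, dj:ny + dj, dk:nz + dk] += 1.0
        elif comp == 1:
            out = np.zeros((nx + 1, ny, nz + 1))
            acc = np.zeros_like(out)
            for di in (0, 1):
                for dk in (0, 1):
                    out[di:nx + di, :, dk:nz + dk] += vol
                    acc[di:nx + di, :, dk:nz + dk] += 1.0
        else:
            out = np.zeros((nx + 1, ny + 1, nz))
            acc = np.zeros_like(out)
            for di in (0, 1):
                for dj in (0, 1):
                    out[di:nx + di, dj:ny + dj, :] += vol
                    acc[di:nx + di, dj:ny + dj, :] += 1.0
        return out / acc

    def _build_coeffs(self, eps_r, sigma):
        dt = self.dt
        self.Ca = []
        self.Cb = []
        for comp in range(3):
            er = self._edge_avg(eps_r, comp)
            sg = self._edge_avg(sigma, comp)
            e = er * EPS0
            a = sg * dt / (2.0 * e)
            self.Ca.append(((1.0 - a) / (1.0 + a)).astype(np.float32))
            self.Cb.append(((dt / e) / (1.0 + a)).astype(np.float32))

    def _build_pml(self):
        cfg = self.config
        prof = [
            _cpml_profiles(n, cfg.pml_cells, self.dx, self.dt,
                           cfg.pml_order, cfg.pml_sigma_factor, cfg.pml_alpha)
            for n in self.shape
        ]
        self.bn = [p[0].astype(np.float32) for p in prof]
        self.cn = [p[1].astype(np.float32) for p in prof]
        self.bc = [p[2].astype(np.float32) for p in prof]
        self.cc = [p[3].astype(np.float32) for p in prof]

    # ---- wires -----------------------------------------------------------
    def wire_indices(self, spec: DipoleSpec):
        """(arm Ex-edge index arrays, port edge index) for an x-axis wire."""
        if abs(abs(np.asarray(spec.axis)[0]) - 1.0) > 1e-9:
            raise NotImplementedError("wires must run along x")
        d = self.config.spacing
        f = np.asarray(spec.feed_position, float)
        # port edge: the Ex edge whose center is nearest the feed x
        ip = int(np.rint(f[0] / d)) - self.i_lo[0]
        # wire transverse position snaps to the node lattice (half-integers)
        jp = int(np.rint(f[1] / d - 0.5)) - self.i_lo[1] + 1
        kp = int(np.rint(f[2] / d - 0.5)) - self.i_lo[2] + 1
        n_arm = max(1, int(np.rint(spec.arm_length / d)))
        arm_i = np.concatenate([
            np.arange(ip - n_arm, ip), np.arange(ip + 1, ip + n_arm + 1)
        ])
        nx = self.shape[0]
        if arm_i.min() < 1 or arm_i.max() >= nx - 1:
            raise ValueError("wire does not fit inside the domain")
        return arm_i, (ip, jp, kp), n_arm


def _port_current(Hy, Hz, ip, jp, kp, dx):
    """Loop integral of H around the port Ex edge (A), current along +x."""
    return dx * (
        (Hz[ip, jp, kp] - Hz[ip, jp - 1, kp])
        - (Hy[ip, jp, kp] - Hy[ip, jp, kp - 1])
    )


def _run(dom: _Domain, spec: DipoleSpec, *, harmonic: bool,
         f0: float | None = None, n_steps: int | None = None,
         record_probe=None, current_probes=None):
    """Time-step one dipole.  Harmonic mode demodulates field phasors;
    pulse mode records the port time series only."""
    cfg = dom.config
    nx, ny, nz = dom.shape
    dx, dt = dom.dx, dom.dt
    inv_d = np.float32(1.0 / dx)
    dtmu = np.float32(dt / MU0)

    f32 = np.float32
    Ex = np.zeros((nx, ny + 1, nz + 1), dtype=f32)
    Ey = np.zeros((nx + 1, ny, nz + 1), dtype=f32)
    Ez = np.zeros((nx + 1, ny + 1, nz), dtype=f32)
    Hx = np.zeros((nx + 1, ny, nz), dtype=f32)
    Hy = np.zeros((nx, ny + 1, nz), dtype=f32)
    Hz = np.zeros((nx, ny, nz + 1), dtype=f32)
    psiE = [np.zeros_like(a) for a in (Ex, Ex, Ey, Ey, Ez, Ez)]
    psiH = [np.zeros_like(a) for a in (Hx, Hx, Hy, Hy, Hz, Hz)]

    CaX, CaY, CaZ = [c.copy() for c in dom.Ca]
    CbX, CbY, CbZ = [c.copy() for c in dom.Cb]

    arm_i, (ip, jp, kp), _ = dom.wire_indices(spec)
    CaX[arm_i, jp, kp] = 0.0
    CbX[arm_i, jp, kp] = 0.0
    # resistive voltage source on the port edge (lumped R across one cell)
    R = spec.source_resistance
    beta = dt / (2.0 * R * EPS0 * dx)
    CaX[ip, jp, kp] = (1.0 - beta) / (1.0 + beta)
    CbX[ip, jp, kp] = (dt / EPS0) / (1.0 + beta)
    src_coef = dt / ((1.0 + beta) * R * EPS0 * dx * dx)

    freq = spec.frequency
    period = 1.0 / freq
    omega = 2 * np.pi * freq
    steps_per_period = int(np.ceil(period / dt))
    dt_eff = dt  # demodulate with true dt; windows are whole periods approx

    if harmonic:
        n_ramp = int(cfg.ramp_periods * steps_per_period)
        win = cfg.demod_periods * steps_per_period
        max_steps = cfg.max_periods * steps_per_period
    else:
        assert n_steps is not None
        max_steps = n_steps

    def vs(t):
        if harmonic:
            a = 1.0
            if t < cfg.ramp_periods * period:
                a = 0.5 * (1 - np.cos(np.pi * t / (cfg.ramp_periods * period)))
            return a * spec.amplitude * np.cos(omega * t + np.deg2rad(spec.phase_deg))
        # gaussian-modulated pulse around f0
        tau = 2.0 / (np.pi * 0.6 * f0)   # ~0.6 f0 two-sided bandwidth
        t0 = 4.0 * tau
        return spec.amplitude * np.exp(-(((t - t0) / tau) ** 2)) * np.cos(
            2 * np.pi * f0 * (t - t0)
        )

    v_series = np.zeros(max_steps)
    i_series = np.zeros(max_steps)
    t_series = np.arange(max_steps) * dt_eff
    probes = list(current_probes) if current_probes else []
    ip_series = np.zeros((len(probes), max_steps))

    Sc = [np.zeros_like(a) for a in (Ex, Ey, Ez)]
    Ss = [np.zeros_like(a) for a in (Ex, Ey, Ez)]
    prev_phasor = None
    n_win_samples = 0
    win_start = n_ramp if harmonic else 0
    probe_series = []

    converged = not harmonic
    final_phasors = None
    conv_history: list[float] = []
    step = 0
    while step < max_steps:
        t_e = step * dt_eff
        _step_H(Ex, Ey, Ez, Hx, Hy, Hz, *psiH,
                dom.bc[0], dom.cc[0], dom.bc[1], dom.cc[1], dom.bc[2], dom.cc[2],
                inv_d, dtmu)
        i_series[step] = _port_current(Hy, Hz, ip, jp, kp, dx)
        for q, (pi, pj, pk) in enumerate(probes):
            ip_series[q, step] = _port_current(Hy, Hz, pi, pj, pk, dx)
        _step_E(Ex, Ey, Ez, Hx, Hy, Hz,
                CaX, CbX, CaY, CbY, CaZ, CbZ, *psiE,
                dom.bn[0], dom.cn[0], dom.bn[1], dom.cn[1], dom.bn[2], dom.cn[2],
                inv_d)
        Ex[ip, jp, kp] -= src_coef * vs(t_e + 0.5 * dt_eff)
        t_next = t_e + dt_eff
        v_series[step] = -Ex[ip, jp, kp] * dx
        if record_probe is not None:
            probe_series.append(Ex[record_probe])
        if harmonic and step >= win_start:
            c = np.cos(omega * t_next)
            s = np.sin(omega * t_next)
            for F, a, b in zip((Ex, Ey, Ez), Sc, Ss):
                _accumulate(a, b, F, c, s)
            n_win_samples += 1
            if n_win_samples == win:
                cur = [
                    (2.0 / win) * (a - 1j * b) for a, b in zip(Sc, Ss)
                ]
                if prev_phasor is not None:
                    num = sum(
                        float(np.sum(np.abs(c0 - p0) ** 2))
                        for c0, p0 in zip(cur, prev_phasor)
                    )
                    den = sum(float(np.sum(np.abs(c0) ** 2)) for c0 in cur)
                    conv_history.append(np.sqrt(num / den) if den > 0 else np.inf)
                    if den > 0 and np.sqrt(num / den) < cfg.convergence_tol:
                        converged = True
                        final_phasors = cur
                        step += 1
                        break
                prev_phasor = cur
                for a in Sc:
                    a[:] = 0.0
                for b in Ss:
                    b[:] = 0.0
                n_win_samples = 0
        step += 1
        if not np.isfinite(Ex[ip, jp, kp]):
            raise ConvergenceError("FDTD instability: non-finite port field")

    if harmonic and not converged:
        raise ConvergenceError(
            f"phasor did not settle within {cfg.max_periods} periods "
            f"(window changes: {['%.2e' % h for h in conv_history]})"
        )
    if harmonic and final_phasors is None:
        final_phasors = prev_phasor

    out = {
        "t": t_series[:step], "v": v_series[:step], "i": i_series[:step],
        "dt": dt_eff, "ip": (ip, jp, kp), "dx": dx,
        "probe": np.asarray(probe_series) if record_probe is not None else None,
    }
    if harmonic:
        out["phasors"] = final_phasors
        # port phasors over the last full window(s) of the run
        n_dem = min(step, 8 * steps_per_period)
        sl = slice(step - n_dem, step)
        tE = t_series[sl] + dt_eff           # V sampled after E update
        tH = t_series[sl] + 0.5 * dt_eff     # I sampled at half steps
        out["V"] = 2.0 * np.mean(v_series[sl] * np.exp(-1j * omega * tE))
        out["I"] = 2.0 * np.mean(i_series[sl] * np.exp(-1j * omega * tH))
        out["I_probes"] = np.array([
            2.0 * np.mean(ip_series[q, sl] * np.exp(-1j * omega * tH))
            for q in range(len(probes))
        ])
    return out


def _collocate(phasors, shape):
    """Average edge phasors to cell centers -> (3, nx, ny, nz) complex."""
    nx, ny, nz = shape
    PEx, PEy, PEz = phasors
    E = np.empty((3, nx, ny, nz), dtype=complex)
    E[0] = 0.25 * (PEx[:, :ny, :nz] + PEx[:, 1:, :nz]
                   + PEx[:, :ny, 1:] + PEx[:, 1:, 1:])
    E[1] = 0.25 * (PEy[:nx, :, :nz] + PEy[1:, :, :nz]
                   + PEy[:nx, :, 1:] + PEy[1:, :, 1:])
    E[2] = 0.25 * (PEz[:nx, :ny, :] + PEz[1:, :ny, :]
                   + PEz[:nx, 1:, :] + PEz[1:, 1:, :])
    return E


def fdtd_unit_field(
    phantom,
    dipole: DipoleSpec,
    config: SolverConfig | None = None,
    antenna_index: int = 0,
    background=(1.0, 0.0),
    domain: _Domain | None = None,
    normalize: bool = True,
) -> ComplexFieldVolume:
    """Steady-state phasor field of one dipole at its drive frequency.

    The returned field is normalized to 1 W accepted port power unless
    ``normalize=False``.  ``background`` is the (eps_r, sigma) of the
    medium outside the phantom (vacuum/air by default); pass ``phantom=None``
    for a homogeneous background run.
    """
    config = config or SolverConfig()
    dom = domain or _Domain(phantom, [dipole], config, background=background)
    res = _run(dom, dipole, harmonic=True)
    E = _collocate(res["phasors"], dom.shape)
    p_acc = 0.5 * np.real(res["V"] * np.conj(res["I"]))
    vol = ComplexFieldVolume(
        E=E,
        spacing=config.spacing,
        origin=dom.origin.astype(float),
        antenna_index=antenna_index,
        accepted_power_norm=np.nan,
        port={
            "V": res["V"], "I": res["I"], "P_acc": p_acc,
            "Z_in": res["V"] / res["I"] if res["I"] != 0 else np.inf,
        },
    )
    if normalize:
        vol = normalize_to_power(vol, p_acc)
    return vol


def normalize_to_power(field: ComplexFieldVolume, measured_port_power: float
                       ) -> ComplexFieldVolume:
    """Rescale so the accepted port power is 1 W (E scales as 1/sqrt(P))."""
    if not measured_port_power > 0:
        raise ValueError(f"non-positive port power {measured_port_power}")
    scale = 1.0 / np.sqrt(measured_port_power)
    return ComplexFieldVolume(
        E=field.E * scale,
        spacing=field.spacing,
        origin=field.origin,
        antenna_index=field.antenna_index,
        accepted_power_norm=1.0,
        port={**field.port, "norm_scale": scale},
    )


# ------------------------------------------------------------ port sweep

def s11_db(z_in, z0: float = 50.0, floor_db: float = -100.0) -> np.ndarray:
    """Reflection coefficient vs a real reference impedance, in dB."""
    z_in = np.asarray(z_in, dtype=complex)
    gamma = (z_in - z0) / (z_in + z0)
    mag = np.abs(gamma)
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(mag)
    return np.maximum(db, floor_db)


def port_sweep(
    dipole: DipoleSpec,
    config: SolverConfig | None = None,
    freqs: np.ndarray | None = None,
    f0: float = 1.3e9,
    n_steps: int | None = None,
    background=(1.0, 0.0),
):
    """Broadband port diagnostics of a single dipole in a homogeneous
    background: S11(f) against 50 ohms and input impedance Z_in(f).

    Excites with a Gaussian-modulated pulse centered at ``f0``, records the
    port voltage/current series, and Fourier-transforms them.
    Returns (freqs, s11_db_array, z_in_array).
    """
    config = config or SolverConfig(spacing=2.0, pad_cells=8)
    if freqs is None:
        freqs = np.linspace(0.6e9, 2.0e9, 141)
    dom = _Domain(None, [dipole], config, background=background)
    if n_steps is None:
        n_steps = int(25e-9 / dom.dt)  # free-space ring-down is fast
    res = _run(dom, dipole, harmonic=False, f0=f0, n_steps=n_steps)
    dt = res["dt"]
    tE = res["t"] + dt
    tH = res["t"] + 0.5 * dt
    w = 2 * np.pi * np.asarray(freqs)
    V = (res["v"][None, :] * np.exp(-1j * np.outer(w, tE))).sum(axis=1) * dt
    I = (res["i"][None, :] * np.exp(-1j * np.outer(w, tH))).sum(axis=1) * dt
    if np.any(np.abs(I) == 0):
        raise ZeroDivisionError("zero port current in sweep")
    z_in = V / I
    return np.asarray(freqs), s11_db(z_in), z_in


# ---------------------------------------------------------------- helpers

def extract_on_phantom(field: ComplexFieldVolume, phantom) -> np.ndarray:
    """Complex E restricted to the phantom grid, shape (3, *phantom.shape)."""
    off = np.rint((phantom.origin - field.origin) / field.spacing).astype(int)
    if np.any(off < 0) or np.any(
        off + np.array(phantom.shape) > np.array(field.shape)
    ):
        raise ValueError("phantom grid not contained in the field volume")
    sl = tuple(slice(o, o + s) for o, s in zip(off, phantom.shape))
    return field.E[(slice(None),) + sl]


def save_fields_h5(path, fields: list[ComplexFieldVolume]) -> None:
    with h5py.File(path, "w") as f:
        for vol in fields:
            g = f.create_group(f"antenna_{vol.antenna_index}")
            g.create_dataset("E_real", data=vol.E.real, compression="gzip")
            g.create_dataset("E_imag", data=vol.E.imag, compression="gzip")
            g.attrs["spacing_mm"] = vol.spacing
            g.attrs["origin_mm"] = vol.origin
            g.attrs["accepted_power_norm_W"] = vol.accepted_power_norm
            g.attrs["antenna_index"] = vol.antenna_index


def load_fields_h5(path) -> list[ComplexFieldVolume]:
    out = []
    with h5py.File(path, "r") as f:
        for name in sorted(f, key=lambda s: int(s.split("_")[1])):
            g = f[name]
            out.append(
                ComplexFieldVolume(
                    E=np.asarray(g["E_real"]) + 1j * np.asarray(g["E_imag"]),
                    spacing=float(g.attrs["spacing_mm"]),
                    origin=np.asarray(g.attrs["origin_mm"]),
                    antenna_index=int(g.attrs["antenna_index"]),
                    accepted_power_norm=float(g.attrs["accepted_power_norm_W"]),
                )
            )
    return out
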