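import numpy as np
import pytest

from htplan.bioheat import (
    StabilityError,
    ThermalConfig,
    ThermalModel,
    ThermalState,
    simulate_treatment,
    stability_bound,
    step_bioheat,
    tumor_perfusion,
)
from htplan.phantom import LABELS, VoxelPhantom, uniform_phantom
from htplan.tissues import TissueProperties, build_tissue_table


def plain_tissue(k=0.5, rho=1000.0, C=3500.0, HTR=0.0, HGR=0.0,
                 name="plain"):
    return TissueProperties(name, 1.0, 0.0, rho, C, k, HTR, HGR)


def tumor_box(n=9, spacing=3.0, tumor_label=LABELS["tumor"], zero_hgr=False):
    """Cube of gland with a single central tumor voxel (no air).

    ``zero_hgr`` removes metabolic heating so 37 °C is the exact
    equilibrium (with it, the insulated Q-free steady state sits slightly
    above arterial temperature)."""
    import dataclasses

    table = build_tissue_table()
    gland, tumor = table["gland"], table["tumor"]
    if zero_hgr:
        gland = dataclasses.replace(gland, HGR=0.0)
        tumor = dataclasses.replace(tumor, HGR=0.0)
    labels = np.full((n, n, n), LABELS["gland"], dtype=np.int16)
    c = n // 2
    labels[c, c, c] = tumor_label
    lm = {LABELS["gland"]: gland, tumor_label: tumor}
    origin = -spacing * (n - 1) / 2 * np.ones(3)
    return VoxelPhantom(labels, spacing, origin, lm,
                        tumor_center=(0.0, 0.0, 0.0), tumor_radius=spacing / 2)


def test_tumor_perfusion_shape():
    assert tumor_perfusion(37.0) == pytest.approx(0.8)
    assert tumor_perfusion(1e3) == pytest.approx(0.4)
    assert tumor_perfusion(42.0) == pytest.approx(0.4 + 0.4 * np.exp(-625.0 / 880.0))
    T = np.linspace(37.0, 60.0, 200)
    w = tumor_perfusion(T)
    assert np.all(np.diff(w) <= 0)          # monotone collapse above 37 °C
    assert np.all((w >= 0.4) & (w <= 0.8))


def test_equilibrium_is_exact():
    """Uniform tissue at T_b with no sources is a discrete fixed point."""
    ph = uniform_phantom((6, 6, 6), 3.0, plain_tissue(HTR=30.0))
    cfg = ThermalConfig(h=0.0)
    model = ThermalModel(ph, cfg)
    state = ThermalState(T=np.full(ph.shape, cfg.T_b), time=0.0)
    out = step_bioheat(state, np.zeros(ph.shape), model, dt=1.0)
    assert np.array_equal(out.T, state.T)


def test_uniform_steady_state_matches_ode():
    """Insulated uniform medium: T → T_b + ρ(HGR+SAR)/(ρ_b C_b ρ HTR_SI)."""
    table = build_tissue_table()
    fat = table["fat"]
    ph = uniform_phantom((5, 5, 5), 3.0, fat)
    cfg = ThermalConfig(h=0.0)
    model = ThermalModel(ph, cfg)
    sar = 2.0                                # W/kg
    Q = np.full(ph.shape, fat.rho * sar)
    pc = 1050.0 * 3617.0 * fat.rho * fat.HTR * 1e-6 / 60.0
    t_inf = cfg.T_b + fat.rho * (fat.HGR + sar) / pc
    dt = 0.5 * stability_bound(ph, model=model)
    state = ThermalState(T=np.full(ph.shape, cfg.T_0))
    while state.time < 9000.0:
        state = step_bioheat(state, Q, model, dt)
    elev = t_inf - cfg.T_b
    assert np.all(np.abs(state.T - t_inf) < 0.005 * elev)


def test_slab_matches_fourier_series():
    """Pure-diffusion slab with fixed faces follows the 1-D transient
    series solution at interior probes."""
    tis = plain_tissue(k=0.211, rho=911.0, C=2348.0)
    n = 41
    ph = uniform_phantom((n, 3, 3), 2.0, tis)
    cfg = ThermalConfig(h=0.0)
    model = ThermalModel(ph, cfg)
    T0, Tf = 37.0, 45.0
    fixed = np.zeros(ph.shape, bool)
    fixed[0], fixed[-1] = True, True
    fv = np.full(ph.shape, Tf)
    state = ThermalState(T=np.full(ph.shape, T0))
    state.T[fixed] = Tf
    dt = 0.4 * stability_bound(ph, model=model)
    t_end = 1200.0
    while state.time < t_end - 1e-9:
        step = min(dt, t_end - state.time)
        state = step_bioheat(state, np.zeros(ph.shape), model, step,
                             fixed_mask=fixed, fixed_values=fv)
    L = (n - 1) * 2.0e-3
    alpha = tis.k / (tis.rho * tis.C)
    x = np.arange(n) * 2.0e-3
    series = np.zeros(n)
    for m in range(1, 400, 2):
        series += 4.0 / (m * np.pi) * np.sin(m * np.pi * x / L) * np.exp(
            -alpha * (m * np.pi / L) ** 2 * t_end
        )
    analytic = Tf + (T0 - Tf) * series
    probe = slice(5, n - 5)
    err = np.abs(state.T[probe, 1, 1] - analytic[probe]) / (Tf - T0)
    assert err.max() < 0.01


def test_stability_bound_formula_and_scaling():
    muscle = build_tissue_table()["muscle"]
    ph3 = uniform_phantom((7, 7, 7), 3.0, muscle)
    cfg = ThermalConfig(h=0.0)
    b3 = stability_bound(ph3, cfg)
    d = 3.0e-3
    pc = 1050.0 * 3617.0 * muscle.rho * muscle.HTR * 1e-6 / 60.0
    expected = muscle.rho * muscle.C / (6 * muscle.k / d**2 + pc)
    assert b3 == pytest.approx(expected, rel=1e-12)
    # halving the spacing quarters the bound (up to the perfusion term)
    nop = plain_tissue(k=muscle.k, rho=muscle.rho, C=muscle.C)
    ba = stability_bound(uniform_phantom((7, 7, 7), 3.0, nop), cfg)
    bb = stability_bound(uniform_phantom((7, 7, 7), 1.5, nop), cfg)
    assert ba / bb == pytest.approx(4.0, rel=1e-12)


def test_stability_bound_is_min_over_tissues():
    table = build_tissue_table()
    cfg = ThermalConfig(h=0.0)
    bounds = {
        name: stability_bound(uniform_phantom((8, 8, 8), 3.0, table[name]), cfg)
        for name in ("muscle", "fat")
    }
    labels = np.full((8, 8, 8), 1, dtype=np.int16)
    labels[4:] = 2
    ph = VoxelPhantom(labels, 3.0, np.zeros(3),
                      {1: table["muscle"], 2: table["fat"]})
    assert stability_bound(ph, cfg) == pytest.approx(min(bounds.values()),
                                                     rel=1e-9)


def test_step_rejects_unstable_dt():
    ph = uniform_phantom((5, 5, 5), 3.0, build_tissue_table()["muscle"])
    cfg = ThermalConfig(h=0.0)
    model = ThermalModel(ph, cfg)
    bound = stability_bound(ph, model=model)
    state = ThermalState(T=np.full(ph.shape, 37.0))
    with pytest.raises(StabilityError):
        step_bioheat(state, np.zeros(ph.shape), model, dt=2.0 * bound)


def test_energy_conserved_without_sinks():
    """Insulated two-tissue block, no perfusion/metabolism/Q: harmonic-mean
    face fluxes conserve ρC·T exactly."""
    t1 = plain_tissue(k=0.5, rho=1000.0, C=3500.0, name="a")
    t2 = plain_tissue(k=0.2, rho=900.0, C=2300.0, name="b")
    labels = np.ones((8, 8, 8), dtype=np.int16)
    labels[:, 4:, :] = 2
    ph = VoxelPhantom(labels, 3.0, np.zeros(3), {1: t1, 2: t2})
    cfg = ThermalConfig(h=0.0)
    model = ThermalModel(ph, cfg)
    rng = np.random.default_rng(0)
    state = ThermalState(T=37.0 + 5.0 * rng.random(ph.shape))
    rhoC = model.rhoC
    e0 = float(np.sum(rhoC * state.T))
    dt = 0.5 * stability_bound(ph, model=model)
    for _ in range(50):
        state = step_bioheat(state, np.zeros(ph.shape), model, dt)
    e1 = float(np.sum(rhoC * state.T))
    assert abs(e1 - e0) / abs(e0) < 1e-10


def test_maximum_principle_and_monotone_in_q():
    muscle = build_tissue_table()["muscle"]
    ph = uniform_phantom((7, 7, 7), 3.0, muscle)
    cfg = ThermalConfig(h=0.0)
    model = ThermalModel(ph, cfg)
    rng = np.random.default_rng(1)
    Q = 5e3 * rng.random(ph.shape)
    dt = 0.5 * stability_bound(ph, model=model)

    def run(q):
        s = ThermalState(T=np.full(ph.shape, cfg.T_b))
        for _ in range(200):
            s = step_bioheat(s, q, model, dt)
        return s.T

    T1, T2 = run(Q), run(2 * Q)
    assert T1.min() >= cfg.T_b - 1e-9                  # Q >= 0 never cools
    assert T1.max() <= cfg.T_b + (Q.max() + muscle.rho * muscle.HGR) / 2553 * 1.01
    assert np.all(T2 >= T1 - 1e-12)                     # monotone in Q


def test_linear_tissue_elevation_doubles_with_q():
    tis = plain_tissue(HTR=40.0, HGR=0.0)
    ph = uniform_phantom((6, 6, 6), 3.0, tis)
    cfg = ThermalConfig(h=0.0)
    model = ThermalModel(ph, cfg)
    rng = np.random.default_rng(2)
    Q = 2e3 * rng.random(ph.shape)
    dt = 0.5 * stability_bound(ph, model=model)

    def run(q):
        s = ThermalState(T=np.full(ph.shape, cfg.T_b))
        for _ in range(150):
            s = step_bioheat(s, q, model, dt)
        return s.T - cfg.T_b

    assert np.allclose(run(2 * Q), 2 * run(Q), rtol=1e-10, atol=1e-12)


def test_nonlinear_perfusion_accumulates_more_heat():
    """At equal heating the ω(T) tumor ends hotter than a constant-ω(37)
    tumor: reduced perfusion above 37 °C means less convective cooling."""
    table = build_tissue_table()
    ph_nl = tumor_box()
    # constant-perfusion variant: HTR chosen so ρ_bC_bρHTR_SI = C_b·ω(37)
    htr_const = 0.8 / (1050.0 * table["tumor"].rho) * 6e7
    m = table["muscle"]
    const_tumor = TissueProperties("tumor_const", m.eps_r, m.sigma, m.rho,
                                   m.C, m.k, htr_const, m.HGR)
    ph_c = tumor_box()
    ph_c.label_map = dict(ph_c.label_map)
    ph_c.label_map[LABELS["tumor"]] = const_tumor
    Q = np.zeros(ph_nl.shape)
    c = ph_nl.shape[0] // 2
    Q[c - 1:c + 2, c - 1:c + 2, c - 1:c + 2] = 1e5   # strong focal heating
    cfg = ThermalConfig(h=0.0, exposure_duration=600.0, cooldown_duration=60.0)
    out_nl = simulate_treatment(ph_nl, Q, cfg)
    out_c = simulate_treatment(ph_c, Q, cfg)
    t_nl = out_nl["T_end_exposure"][c, c, c]
    t_c = out_c["T_end_exposure"][c, c, c]
    assert t_nl > 37.5                  # the source actually heats
    assert t_nl >= t_c - 1e-12


def test_treatment_cooldown_is_nonincreasing():
    ph = tumor_box(zero_hgr=True)
    Q = np.zeros(ph.shape)
    c = ph.shape[0] // 2
    Q[c, c, c] = 5e4
    cfg = ThermalConfig(h=0.0, exposure_duration=300.0,
                        cooldown_duration=300.0, record_interval=20.0)
    out = simulate_treatment(ph, Q, cfg)
    mask = out["t"] >= 300.0
    after = out["T_center"][mask]
    assert np.all(np.diff(after) <= 1e-9)
    assert out["per_tissue_max_end_exposure"]["tumor"] >= \
        out["per_tissue_max_end_exposure"]["gland"] - 5.0


def test_treatment_without_source_stays_at_baseline():
    ph = tumor_box(zero_hgr=True)
    cfg = ThermalConfig(h=0.0, exposure_duration=200.0, cooldown_duration=100.0)
    out = simulate_treatment(ph, np.zeros(ph.shape), cfg)
    assert np.all(np.abs(out["T_center"] - 37.0) < 1e-6)
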