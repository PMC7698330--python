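import numpy as np
import pytest

from htplan.dipole import (
    ETA0,
    MU0,
    EPS0,
    ArrayGeometry,
    DipoleSpec,
    analytic_dipole_field,
    complex_wavenumber,
    place_array,
)


def test_place_array_geometry():
    specs = place_array(ArrayGeometry(8, 100.0))
    feeds = np.array([s.feed_position for s in specs])
    assert len(specs) == 8
    assert np.allclose(np.linalg.norm(feeds, axis=1), 100.0)
    assert np.allclose(feeds[:, 0], 0.0)  # sources in the x=0 plane
    ang = np.rad2deg(np.arctan2(feeds[:, 2], feeds[:, 1]))
    d = np.diff(np.unwrap(np.deg2rad(ang)))
    assert np.allclose(np.rad2deg(d), 45.0)
    assert np.allclose(feeds.mean(axis=0), 0.0, atol=1e-9)


def test_place_array_single():
    (s,) = place_array(ArrayGeometry(1, 100.0))
    assert np.allclose(s.feed_position, (0.0, 100.0, 0.0))


def test_place_array_rejects_wire_through_tissue(hd_phantom):
    with pytest.raises(ValueError):
        place_array(ArrayGeometry(8, 40.0), phantom=hd_phantom)


def test_axis_point_has_no_transverse_field():
    dip = DipoleSpec((0.0, 0.0, 0.0))
    E = analytic_dipole_field(dip, [(200.0, 0.0, 0.0)], 1.0, 0.0)
    assert abs(E[0, 1]) == 0.0 and abs(E[0, 2]) == 0.0
    assert abs(E[0, 0]) > 0.0  # axial component survives in the near zone


def test_lossy_decay_faster_than_inverse_r():
    dip = DipoleSpec((0.0, 0.0, 0.0))
    pts = [(0.0, 300.0, 0.0), (0.0, 600.0, 0.0)]
    El = analytic_dipole_field(dip, pts, 5.41, 0.053)
    ratio_lossy = np.linalg.norm(El[1]) / np.linalg.norm(El[0])
    E0 = analytic_dipole_field(dip, pts, 5.41, 0.0)
    ratio_ll = np.linalg.norm(E0[1]) / np.linalg.norm(E0[0])
    assert ratio_lossy < ratio_ll < 1.0


def test_point_inside_wire_rejected():
    dip = DipoleSpec((0.0, 0.0, 0.0))
    with pytest.raises(ValueError):
        analytic_dipole_field(dip, [(10.0, 0.5, 0.0)], 1.0, 0.0)


def _quadrature_field(dip, pts_mm, eps_r, sigma, i_max, h_mm, n_seg=4000):
    """Independent oracle: superpose exact infinitesimal-dipole fields of a
    sinusoidal current distribution by numeric quadrature."""
    f = dip.frequency
    omega = 2 * np.pi * f
    k = complex_wavenumber(eps_r, sigma, f)
    eps_c = EPS0 * eps_r - 1j * sigma / omega
    eta = np.sqrt(MU0 / eps_c)
    h = h_mm * 1e-3
    zs = (np.arange(n_seg) + 0.5) / n_seg * 2 * h - h  # along the x axis
    dz = 2 * h / n_seg
    I = i_max * np.sin(k * (h - np.abs(zs)))
    out = np.zeros((len(pts_mm), 3), dtype=complex)
    for pt_i, pt in enumerate(np.asarray(pts_mm, float) * 1e-3):
        for z0, Iz in zip(zs, I):
            rel = pt - np.array([z0, 0.0, 0.0])
            r = np.linalg.norm(rel)
            ct = rel[0] / r
            st = np.sqrt(max(1.0 - ct**2, 0.0))
            ikr = 1j * k * r
            ph = np.exp(-ikr)
            Er = eta * Iz * dz * ct / (2 * np.pi * r**2) * (1 + 1 / ikr) * ph
            Et = (
                1j * eta * k * Iz * dz * st / (4 * np.pi * r)
                * (1 + 1 / ikr - 1 / (k * r) ** 2) * ph
            )
            r_hat = rel / r
            # theta_hat in the plane of r_hat and the x axis
            x_hat = np.array([1.0, 0.0, 0.0])
            t_vec = ct * r_hat - x_hat
            tn = np.linalg.norm(t_vec)
            t_hat = t_vec / tn if tn > 1e-12 else np.zeros(3)
            out[pt_i] += Er * r_hat + Et * t_hat
    return out


def test_closed_form_matches_quadrature_half_wave():
    """The three-ray closed form equals segment-by-segment integration of
    the sinusoidal current (half-wave case, lossless and lossy)."""
    dip = DipoleSpec((0.0, 0.0, 0.0), arm_length=74.0, gap=2.0)  # h = 75 = λ/4
    pts = [(0.0, 120.0, 0.0), (80.0, 140.0, 0.0), (50.0, 60.0, 90.0)]
    for eps_r, sigma in ((1.0, 0.0), (5.41, 0.053)):
        Ec = analytic_dipole_field(
            dip, pts, eps_r, sigma,
            feed_current=np.sin(complex_wavenumber(eps_r, sigma, 1e9) * 0.075),
            half_length_mm=75.0,
        )
        Eq = _quadrature_field(dip, pts, eps_r, sigma, 1.0, 75.0)
        for a, b in zip(Ec, Eq):
            assert np.linalg.norm(a - b) / np.linalg.norm(b) < 2e-3


def test_equatorial_pattern_maximum():
    dip = DipoleSpec((0.0, 0.0, 0.0), arm_length=74.0, gap=2.0)
    r = 2000.0
    angles = np.linspace(0.05, np.pi / 2, 30)
    pts = [(r * np.cos(a), r * np.sin(a), 0.0) for a in angles]
    E = analytic_dipole_field(dip, pts, 1.0, 0.0, half_length_mm=75.0)
    mags = np.linalg.norm(E, axis=1)
    assert np.argmax(mags) == len(angles) - 1  # max at the equator
    # sin-like: monotone growth from axis to equator
    assert np.all(np.diff(mags) > 0)


def test_shortening_factor_convention():
    dip = DipoleSpec((0.0, 0.0, 0.0))
    assert dip.wavelength == pytest.approx(299.792458)
    assert dip.shortening_factor == pytest.approx(0.67, abs=0.01)
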