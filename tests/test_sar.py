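import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from htplan.phantom import generate_breast_phantom
from htplan.sar import (
    ExcitationVector,
    SarQuadraticForm,
    build_quadratic_form,
    combine_fields,
    pointwise_sar,
    sar_map,
    sar_vol,
)
from .conftest import make_synthetic_fields


def brute_force_sar(fields, excitation, sigma, rho):
    """Independent oracle: the N² trigonometric double sum over antenna
    pairs, written in amplitude/phase (not complex) arithmetic."""
    P = np.asarray(excitation.powers)
    phi = np.deg2rad(excitation.phases_deg)
    A = np.sqrt(P)
    Em = np.stack([np.abs(f.E) for f in fields])     # (N, 3, ...)
    Ph = np.stack([np.angle(f.E) for f in fields])
    n = len(fields)
    out = np.zeros(fields[0].E.shape[1:])
    for m in range(n):
        for q in range(n):
            out += A[m] * A[q] * np.sum(
                Em[m] * Em[q] * np.cos(Ph[q] - Ph[m] + phi[q] - phi[m]),
                axis=0,
            )
    return sigma / (2.0 * rho) * out


def random_excitation(rng, n=8, total=8.0):
    p = rng.dirichlet(np.ones(n)) * total
    ph = rng.uniform(-180.0, 180.0, n)
    ph[-1] = 0.0
    return ExcitationVector(tuple(p), tuple(ph))


def test_pointwise_sar_values():
    E = np.zeros((3, 1)); E[0, 0] = 100.0
    assert pointwise_sar(E, 0.978, 1090.0)[0] == pytest.approx(
        0.978 * 1e4 / (2 * 1090.0)
    )
    assert pointwise_sar(np.zeros((3, 4)), 1.0, 1000.0).max() == 0.0
    assert pointwise_sar(E, 0.0, 1000.0)[0] == 0.0
    with pytest.raises(ValueError):
        pointwise_sar(E, 1.0, 0.0)


def test_combine_identity_and_cancellation(synthetic_fields):
    one = ExcitationVector((1.0,) + (0.0,) * 7, (0.0,) * 8)
    out = combine_fields(synthetic_fields, one)
    assert np.allclose(out.E, synthetic_fields[0].E)

    twin = [synthetic_fields[0], synthetic_fields[0]]
    anti = ExcitationVector((2.0, 2.0), (0.0, 180.0))
    assert np.abs(combine_fields(twin, anti).E).max() < 1e-12


def test_combined_sar_matches_trig_oracle(synthetic_fields):
    """Complex superposition + σ|E|²/2ρ equals the amplitude/phase double
    sum at randomly chosen voxels."""
    rng = np.random.default_rng(7)
    sigma, rho = 0.9, 1050.0
    exc = random_excitation(rng)
    sar = pointwise_sar(combine_fields(synthetic_fields, exc).E, sigma, rho)
    oracle = brute_force_sar(synthetic_fields, exc, sigma, rho)
    idx = tuple(rng.integers(0, 10, size=(3, 50)))
    assert np.allclose(sar[idx], oracle[idx], rtol=1e-10, atol=1e-12)


def test_quadratic_form_single_antenna_collapses(synthetic_fields):
    f = [synthetic_fields[0]]
    mask = np.ones(f[0].E.shape[1:], bool)
    sigma = np.full(mask.shape, 0.9)
    rho = np.full(mask.shape, 1050.0)
    form = build_quadratic_form(f, mask, sigma, rho)
    mean_sar = pointwise_sar(f[0].E, sigma, rho).mean()
    assert form.H.shape == (1, 1)
    assert form.H[0, 0].real == pytest.approx(mean_sar, rel=1e-12)
    assert form.H[0, 0].imag == pytest.approx(0.0, abs=1e-15)


def test_single_voxel_region_equals_pointwise(synthetic_fields):
    rng = np.random.default_rng(3)
    mask = np.zeros(synthetic_fields[0].E.shape[1:], bool)
    mask[4, 5, 6] = True
    sigma = np.full(mask.shape, 1.1)
    rho = np.full(mask.shape, 911.0)
    form = build_quadratic_form(synthetic_fields, mask, sigma, rho)
    for _ in range(20):
        exc = random_excitation(rng)
        direct = pointwise_sar(
            combine_fields(synthetic_fields, exc).E, 1.1, 911.0
        )[4, 5, 6]
        assert sar_vol(form, exc) == pytest.approx(direct, rel=1e-10)


def test_form_is_hermitian_psd(synthetic_fields):
    mask = np.ones(synthetic_fields[0].E.shape[1:], bool)
    sigma = np.full(mask.shape, 0.5)
    rho = np.full(mask.shape, 1000.0)
    form = build_quadratic_form(synthetic_fields, mask, sigma, rho)
    assert np.array_equal(form.H, form.H.conj().T)
    evals = np.linalg.eigvalsh(form.H)
    assert evals.min() >= -1e-12 * evals.max()
    assert np.all(np.diag(form.H).real >= 0)
    assert np.all(np.abs(np.diag(form.H).imag) < 1e-15)


def test_sar_vol_mean_oracle(synthetic_fields):
    rng = np.random.default_rng(11)
    mask = rng.random(synthetic_fields[0].E.shape[1:]) < 0.5
    sigma = rng.uniform(0.05, 1.6, mask.shape)
    rho = rng.uniform(900, 1100, mask.shape)
    form = build_quadratic_form(synthetic_fields, mask, sigma, rho)
    exc = random_excitation(rng)
    direct = pointwise_sar(combine_fields(synthetic_fields, exc).E, sigma, rho)
    assert sar_vol(form, exc) == pytest.approx(direct[mask].mean(), rel=1e-9)


@given(shift=st.floats(-180.0, 180.0), scale=st.floats(0.1, 10.0))
@settings(max_examples=25, deadline=None)
def test_gauge_and_scale_invariance(shift, scale):
    """Region SAR is invariant under a common phase shift; scaling all
    powers scales SARvol linearly."""
    fields = make_synthetic_fields(n_antennas=4, shape=(5, 5, 5), seed=2)
    mask = np.ones((5, 5, 5), bool)
    form = build_quadratic_form(fields, mask, np.full(mask.shape, 1.0),
                                np.full(mask.shape, 1000.0))
    rng = np.random.default_rng(0)
    exc = random_excitation(rng, n=4)
    base = sar_vol(form, exc)
    shifted = ExcitationVector(
        exc.powers,
        tuple(((np.asarray(exc.phases_deg) + shift + 180) % 360) - 180),
    )
    assert sar_vol(form, shifted) == pytest.approx(base, rel=1e-9)
    scaled = ExcitationVector(tuple(scale * p for p in exc.powers),
                              exc.phases_deg)
    assert sar_vol(form, scaled) == pytest.approx(scale * base, rel=1e-9)


def test_disjoint_region_sum_rule(synthetic_fields):
    """SARvol over a union of equal-count disjoint regions is the mean of
    the per-region SARvol."""
    shape = synthetic_fields[0].E.shape[1:]
    m1 = np.zeros(shape, bool); m1[:5] = True
    m2 = np.zeros(shape, bool); m2[5:] = True
    sigma = np.full(shape, 0.8); rho = np.full(shape, 1000.0)
    f1 = build_quadratic_form(synthetic_fields, m1, sigma, rho)
    f2 = build_quadratic_form(synthetic_fields, m2, sigma, rho)
    fu = build_quadratic_form(synthetic_fields, m1 | m2, sigma, rho)
    exc = random_excitation(np.random.default_rng(1))
    assert sar_vol(fu, exc) == pytest.approx(
        0.5 * (sar_vol(f1, exc) + sar_vol(f2, exc)), rel=1e-12
    )


def test_zero_power_gives_zero(synthetic_fields):
    mask = np.ones(synthetic_fields[0].E.shape[1:], bool)
    form = build_quadratic_form(synthetic_fields, mask,
                                np.full(mask.shape, 1.0),
                                np.full(mask.shape, 1000.0))
    zero = ExcitationVector((0.0,) * 8, (0.0,) * 8)
    assert sar_vol(form, zero) == 0.0


def test_empty_region_rejected(synthetic_fields):
    mask = np.zeros(synthetic_fields[0].E.shape[1:], bool)
    with pytest.raises(ValueError):
        build_quadratic_form(synthetic_fields, mask,
                             np.full(mask.shape, 1.0),
                             np.full(mask.shape, 1000.0))


def test_excitation_validation():
    with pytest.raises(ValueError):
        ExcitationVector((1.0, -0.5), (0.0, 0.0))
    with pytest.raises(ValueError):
        ExcitationVector((1.0, 1.0), (0.0, 200.0))
    exc = ExcitationVector.from_amplitudes([1 + 1j, 2j])
    assert exc.phases_deg[-1] == 0.0
    assert exc.total_power == pytest.approx(6.0)


def test_sar_map_db_conventions():
    ph = generate_breast_phantom(seed=1)
    fields = make_synthetic_fields(
        n_antennas=2, shape=ph.shape, spacing=ph.spacing, origin=ph.origin,
        seed=4,
    )
    exc = ExcitationVector((4.0, 4.0), (30.0, 0.0))
    sar, db = sar_map(fields, exc, ph)
    tissue = ph.labels != 0
    assert np.nanmax(db) == 0.0
    assert np.all(np.isnan(db[~tissue]))
    # dB is a monotone transform: ranking preserved
    s = sar[tissue]; d = db[tissue]
    order = np.argsort(s)
    assert np.all(np.diff(d[order]) >= 0)
    i = np.unravel_index(np.nanargmax(np.where(tissue, sar, -1)), sar.shape)
    near = np.abs(sar - sar[i] / 10.0)
    j = np.unravel_index(np.argmin(np.where(tissue, near, np.inf)), sar.shape)
    assert db[j] == pytest.approx(10 * np.log10(sar[j] / sar[i]), abs=1e-12)


def test_hermitian_constructor_guard():
    with pytest.raises(ValueError):
        SarQuadraticForm(H=np.array([[1.0, 2.0], [0.5, 1.0]]), voxel_count=1)
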