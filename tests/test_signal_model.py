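import numpy as np
import pytest
from scipy.linalg import expm

from cestqmt import (
    AcquisitionSchedule,
    Pool,
    PoolSystem,
    SaturationScheme,
    SteadyStateModel,
    build_relaxation_matrix,
    build_saturation_matrix,
    simulate_zspectrum,
    steady_state_magnetization,
)
from cestqmt.signal_model import _excitation_matrix, _spoil_matrix

from conftest import random_scheme, random_system


def iterate_cycle(system, scheme, offset_ppm, omega1, exc_flip_deg,
                  n_iter=200000, tol=1e-13):
    """Independent oracle: apply the shot cycle step by step from
    equilibrium until the pre-saturation state converges."""
    r_l = build_relaxation_matrix(system)
    w = build_saturation_matrix(system, offset_ppm, omega1)
    m0 = system.m0_vec()
    a_sat = r_l + w
    m_ss = np.linalg.solve(a_sat, r_l @ m0)
    e_m = expm(a_sat * scheme.t_m)
    e_s = expm(r_l * scheme.t_s)
    e_r = expm(r_l * scheme.t_r)
    S = _spoil_matrix(system)
    C = _excitation_matrix(system, exc_flip_deg)

    m = m0.copy()
    for _ in range(n_iter):
        sat = e_m @ (m - m_ss) + m_ss
        pre_exc = e_s @ (S @ sat - m0) + m0
        m_next = S @ (e_r @ (C @ (S @ pre_exc) - m0) + m0)
        if np.max(np.abs(m_next - m)) < tol:
            return e_s @ (S @ (e_m @ (m_next - m_ss) + m_ss) - m0) + m0
        m = m_next
    raise AssertionError("iterated cycle did not converge")


def test_relaxation_matrix_water_only(water_pool):
    sys1 = PoolSystem([water_pool])
    R = build_relaxation_matrix(sys1)
    np.testing.assert_allclose(
        R, np.diag([-water_pool.r2, -water_pool.r2, -water_pool.r1])
    )


def test_relaxation_matrix_three_pool_water_z_row(brain3):
    """Water z row couples to every solute z with the forward rates, and
    its diagonal carries R1F plus the total outflux."""
    R = build_relaxation_matrix(brain3)
    amide, mt = brain3.get("amide"), brain3.get("semisolid")
    k_fs = amide.k_to_water * amide.m0r
    k_fm = mt.k_to_water * mt.m0r
    row = np.zeros(7)
    row[2] = -brain3.get("water").r1 - k_fs - k_fm
    row[5] = amide.k_to_water
    row[6] = mt.k_to_water
    np.testing.assert_allclose(R[2], row, atol=1e-14)
    # transverse water diagonal excludes the semisolid exchange term
    assert R[0, 0] == pytest.approx(-brain3.get("water").r2 - k_fs)


def test_detailed_balance_gives_minus_r1_m0(brain3):
    """R_L @ M0 has z components (-R1F, -R1S*m0rS, -R1M*m0rM)."""
    R = build_relaxation_matrix(brain3)
    v = R @ brain3.m0_vec()
    amide, mt = brain3.get("amide"), brain3.get("semisolid")
    np.testing.assert_allclose(v[[0, 1, 3, 4]], 0.0, atol=1e-15)
    assert v[2] == pytest.approx(-brain3.get("water").r1)
    assert v[5] == pytest.approx(-amide.r1 * amide.m0r)
    assert v[6] == pytest.approx(-mt.r1 * mt.m0r)


def test_exchange_conserves_total_z(brain3):
    """With relaxation removed, the exchange network conserves the summed
    longitudinal magnetization (zero column sums over z rows)."""
    stripped = PoolSystem(
        [p.with_(t1=1e12, t2=1e12) if p.klass == "mobile" else p.with_(t1=1e12)
         for p in brain3.pools]
    )
    R = build_relaxation_matrix(stripped)
    z_rows = [stripped.z_index(p) for p in stripped.pools]
    col_sums = R[np.ix_(z_rows, z_rows)].sum(axis=0)
    np.testing.assert_allclose(col_sums, 0.0, atol=1e-9)


def test_saturation_matrix_structure(brain3):
    w1 = 300.0
    W = build_saturation_matrix(brain3, 3.5, w1)
    # amide on resonance: its precession block vanishes
    assert W[3, 4] == pytest.approx(0.0)
    # water precesses at 3.5 ppm * 127.7 Hz/ppm
    assert W[0, 1] == pytest.approx(2 * np.pi * 3.5 * 127.7)
    # nutation terms
    assert W[1, 2] == pytest.approx(-w1)
    assert W[2, 1] == pytest.approx(w1)
    # semisolid diagonal is the (negative) lineshape absorption rate
    assert W[6, 6] < 0
    W0 = build_saturation_matrix(brain3, 3.5, 0.0)
    assert W0[6, 6] == 0.0
    assert W0[1, 2] == 0.0


def test_ppm_to_hz_linear_in_center_freq(brain3):
    hi = PoolSystem([p for p in brain3.pools], center_freq_mhz=300.0)
    W_lo = build_saturation_matrix(brain3, 2.0, 0.0)
    W_hi = build_saturation_matrix(hi, 2.0, 0.0)
    assert W_hi[0, 1] == pytest.approx(W_lo[0, 1] * 300.0 / 127.7)


def test_equilibrium_without_rf(brain3, scheme180):
    m = steady_state_magnetization(brain3, scheme180.__class__(
        sat_flip_deg=0.0, exc_flip_deg=0.0), 3.5, 0.0)
    np.testing.assert_allclose(m, brain3.m0_vec(), atol=1e-12)


def test_far_off_resonance_matches_rf_off(brain3, scheme180):
    model = SteadyStateModel(brain3, scheme180)
    w1 = scheme180.cwep_omega1()
    far = model.water_z(1e6, w1)
    off = model.water_z(1e6, 0.0)
    assert far == pytest.approx(off, abs=1e-6)


def test_closed_form_equals_iterated_cycle(brain3, scheme180):
    w1 = scheme180.cwep_omega1()
    for off in (-3.5, 0.3, 3.5, 15.0):
        closed = steady_state_magnetization(brain3, scheme180, off, w1)
        iterated = iterate_cycle(brain3, scheme180, off, w1, 7.0)
        np.testing.assert_allclose(closed, iterated, rtol=0, atol=1e-10)


def test_closed_form_equals_iterated_cycle_randomized():
    """Randomized spot check of the fixed-point identity (the full
    100-system sweep runs in the acceptance suite)."""
    rng = np.random.default_rng(1234)
    for _ in range(10):
        system = random_system(rng)
        scheme = random_scheme(rng)
        w1 = scheme.cwep_omega1()
        off = rng.uniform(-10, 10)
        closed = steady_state_magnetization(system, scheme, off, w1)
        iterated = iterate_cycle(system, scheme, off, w1, scheme.exc_flip_deg)
        scale = max(1e-3, float(np.max(np.abs(iterated))))
        assert np.max(np.abs(closed - iterated)) / scale < 1e-8


def test_water_only_spectrum_symmetric(water_pool, scheme180):
    sys1 = PoolSystem([water_pool])
    offs = np.array([-3.0, -1.0, -0.3, 0.3, 1.0, 3.0, 800.0])
    z = simulate_zspectrum(sys1, scheme180,
                           AcquisitionSchedule(offs, np.full(7, 180.0)))
    np.testing.assert_allclose(z.values[:3], z.values[3:6][::-1], atol=1e-12)


def test_solute_adds_saturation_at_its_offset(water_pool, scheme180):
    sys1 = PoolSystem([water_pool])
    sys2 = PoolSystem([water_pool, Pool("amide", 3.5, 1.0, 0.01, 0.005, 30.0)])
    sched = AcquisitionSchedule(np.array([3.5, 800.0]), np.full(2, 180.0))
    z1 = simulate_zspectrum(sys1, scheme180, sched)
    z2 = simulate_zspectrum(sys2, scheme180, sched)
    assert z2.values[0] < z1.values[0]


def test_zero_m0r_equals_pool_removed(brain3, scheme180, small_schedule):
    zeroed = brain3.replace_pool("amide", m0r=0.0)
    removed = brain3.without("amide")
    za = simulate_zspectrum(zeroed, scheme180, small_schedule)
    zb = simulate_zspectrum(removed, scheme180, small_schedule)
    np.testing.assert_allclose(za.values, zb.values, atol=1e-10)


def test_water_z_decreases_with_semisolid_m0r(brain3, scheme180):
    """PSR monotonicity: more semisolid means less water signal at 15 ppm."""
    w1 = scheme180.cwep_omega1()
    values = []
    for m0r in (0.05, 0.1, 0.2, 0.3):
        sys_ = brain3.replace_pool("semisolid", m0r=m0r)
        values.append(SteadyStateModel(sys_, scheme180).water_z(15.0, w1))
    assert all(a > b for a, b in zip(values, values[1:]))


def test_b1_scale_deepens_saturation(brain3, scheme180, small_schedule):
    model = SteadyStateModel(brain3, scheme180)
    z1 = model.zspectrum(small_schedule, b1_scale=1.0)
    z2 = model.zspectrum(small_schedule, b1_scale=1.3)
    assert z2.values[3] < z1.values[3]


def test_b0_shift_moves_spectrum(brain3, scheme180):
    offs = np.linspace(-1, 1, 21)
    sched = AcquisitionSchedule(np.append(offs, 800.0), np.full(22, 180.0))
    model = SteadyStateModel(brain3, scheme180)
    z0 = model.zspectrum(sched).values[:-1]
    z1 = model.zspectrum(sched, b0_shift_ppm=0.3).values[:-1]
    assert offs[np.argmin(z1)] - offs[np.argmin(z0)] == pytest.approx(0.3, abs=0.11)
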