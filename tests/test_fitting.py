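import numpy as np
import pytest

from cestqmt import (
    FitConfig,
    ParameterPrior,
    SaturationScheme,
    estimate_t1,
    fit_image,
    fit_qmt_fix,
    fit_spectrum,
    invivo_schedule,
    make_pool_system,
    mtr_star,
    simulate_zspectrum,
)
from cestqmt.fitting import LOG10, default_priors


@pytest.fixture(scope="module")
def phantom_truth():
    return make_pool_system("bsa_agarose", (6.0, 0.65))


@pytest.fixture(scope="module")
def scheme():
    return SaturationScheme()


@pytest.fixture(scope="module")
def schedule():
    return invivo_schedule()


@pytest.fixture(scope="module")
def clean_z(phantom_truth, scheme, schedule):
    return simulate_zspectrum(phantom_truth, scheme, schedule)


def rel_err(a, b):
    return abs(a - b) / abs(b)


def test_noiseless_self_consistency(phantom_truth, scheme, schedule, clean_z):
    """Fitting data generated by the model's own forward model with priors
    centred at truth returns the truth."""
    cfg = FitConfig(system=phantom_truth, scheme=scheme, seed=0)
    est = fit_spectrum(clean_z, None, cfg)
    for p in phantom_truth.pools[1:]:
        for par in ("m0r", "k_to_water", "t2"):
            assert rel_err(getattr(est.system.get(p.name), par),
                           getattr(p, par)) < 1e-3
    assert abs(est.b0_shift_ppm) < 1e-4
    assert est.residual_rms < 1e-6


def test_two_pool_noiseless_recovery(phantom_truth, scheme, schedule):
    truth2 = phantom_truth.without("amide", "noe")
    z = simulate_zspectrum(truth2, scheme, schedule)
    est = fit_spectrum(z, None, FitConfig(system=truth2, scheme=scheme))
    mt = truth2.get("semisolid")
    assert rel_err(est.psr, mt.m0r) < 1e-3
    assert rel_err(est.system.get("semisolid").k_to_water, mt.k_to_water) < 1e-3
    assert rel_err(est.system.get("semisolid").t2, mt.t2) < 1e-3


def test_prior_dominance(phantom_truth, scheme, schedule, clean_z):
    """As a parameter's prior sd shrinks to zero the estimate collapses to
    the prior mean."""
    wrong = 0.030  # true semisolid m0r is 0.0195
    priors = default_priors(phantom_truth)
    priors[("semisolid", "m0r")] = ParameterPrior(wrong, 1e-6, log_domain=True)
    cfg = FitConfig(system=phantom_truth, scheme=scheme, priors=priors)
    est = fit_spectrum(clean_z, None, cfg)
    assert est.psr == pytest.approx(wrong, rel=1e-3)


def test_b0_equivariance(phantom_truth, scheme, schedule, clean_z):
    """Shifting every schedule offset by delta is absorbed by the fitted
    B0, leaving the other parameters unchanged."""
    delta = 0.15
    shifted = schedule.__class__(
        schedule.offsets_ppm + delta, schedule.sat_flips_deg
    )
    cfg = FitConfig(system=phantom_truth, scheme=scheme,
                    b0_prior=ParameterPrior(0.0, 0.3))
    est = fit_spectrum(clean_z.values, shifted, cfg)
    assert est.b0_shift_ppm == pytest.approx(delta, abs=0.02)
    assert rel_err(est.psr, phantom_truth.get("semisolid").m0r) < 0.01


def test_insufficient_data_raises(phantom_truth, scheme):
    from cestqmt import AcquisitionSchedule

    sched = AcquisitionSchedule(np.array([3.5, 800.0]), np.full(2, 184.0))
    cfg = FitConfig(system=phantom_truth, scheme=scheme)
    with pytest.raises(ValueError):
        fit_spectrum(np.array([0.8, 1.0]), sched, cfg)
    with pytest.raises(ValueError):
        ParameterPrior(1.0, -0.1)


def test_qmt_fix_stages(phantom_truth, scheme, schedule, clean_z):
    """Stage 1 recovers the MT pool from the qMT points; stage 2 fixes it
    and the derived amide effect tracks the truth."""
    cfg = FitConfig(system=phantom_truth, scheme=scheme, seed=2)
    s1, s2 = fit_qmt_fix(clean_z, None, cfg)
    mt = phantom_truth.get("semisolid")
    assert rel_err(s1.psr, mt.m0r) < 0.05  # CEST pools contribute little > 5 ppm
    assert s2.params[("semisolid", "m0r")][1] == 0.0  # fixed in stage 2
    am = s2.system.get("amide")
    truth_mtr = mtr_star(phantom_truth.get("amide").m0r, 30.0, scheme, 3.5)
    fit_mtr = mtr_star(am.m0r, am.k_to_water, scheme, 3.5)
    assert fit_mtr == pytest.approx(truth_mtr, rel=0.35)


def test_qmt_fix_requires_qmt_points(phantom_truth, scheme):
    from cestqmt import AcquisitionSchedule

    sched = AcquisitionSchedule(np.array([-3.5, 3.5, 800.0]), np.full(3, 184.0))
    z = simulate_zspectrum(phantom_truth, scheme, sched)
    with pytest.raises(ValueError):
        fit_qmt_fix(z, None, FitConfig(system=phantom_truth, scheme=scheme))


def test_qmt_fix_on_pure_two_pool_truth(phantom_truth, scheme, schedule):
    """With no CEST pools in the truth, stage-2 CEST amplitudes drop to
    the noise floor."""
    truth2 = phantom_truth.without("amide", "noe")
    z = simulate_zspectrum(truth2, scheme, schedule)
    cfg = FitConfig(system=phantom_truth, scheme=scheme, seed=3)
    _s1, s2 = fit_qmt_fix(z, None, cfg)
    am = s2.system.get("amide")
    assert am.m0r * am.k_to_water < 0.02  # exchange flux ~ zero


def test_mtr_star_properties(scheme):
    assert mtr_star(0.0, 30.0, scheme, 3.5) == 0.0
    grid = [mtr_star(m, 30.0, scheme, 3.5) for m in (0.001, 0.003, 0.01, 0.03)]
    assert all(a < b for a, b in zip(grid, grid[1:]))
    with pytest.raises(ValueError):
        mtr_star(-0.1, 30.0, scheme, 3.5)


def test_estimate_t1_ir_and_vfa():
    tis = np.array([0.1, 0.3, 0.5, 1.0, 1.25, 1.75, 2.0, 2.5, 3.0, 3.5, 4.0])
    sig = np.abs(1000.0 * (1 - 2 * np.exp(-tis / 1.2)))
    t1, _ = estimate_t1(sig, tis, "ir")
    assert t1 == pytest.approx(1.2, rel=1e-6)

    flips = np.array([25.0, 20.0, 15.0, 10.0, 5.0])
    e = np.exp(-0.02 / 1.0)
    rad = np.deg2rad(flips)
    sv = 500.0 * np.sin(rad) * (1 - e) / (1 - e * np.cos(rad))
    t1, _ = estimate_t1(sv, flips, "vfa", tr=0.02)
    assert t1 == pytest.approx(1.0, rel=1e-6)

    with pytest.raises(ValueError):
        estimate_t1(sv, flips, "vfa")  # tr missing
    with pytest.raises(ValueError):
        estimate_t1(sv[:2], flips[:2], "ir")


def test_estimate_t1_ir_noise_bias():
    """1% amplitude noise leaves the IR T1 estimate unbiased to < 1%."""
    tis = np.array([0.1, 0.3, 0.5, 1.0, 1.25, 1.75, 2.0, 2.5, 3.0, 3.5, 4.0])
    clean = 1000.0 * (1 - 2 * np.exp(-tis / 1.2))
    rng = np.random.default_rng(5)
    t1s = [
        estimate_t1(np.abs(clean + rng.normal(0, 10.0, tis.size)), tis, "ir")[0]
        for _ in range(200)
    ]
    assert abs(np.mean(t1s) - 1.2) / 1.2 < 0.01


def test_fit_image_matches_fit_spectrum(phantom_truth, scheme, schedule, clean_z):
    """A single-voxel image reproduces the spectrum fit; a uniform image
    gives identical maps everywhere."""
    data = np.tile(clean_z.values, (1, 2, 1))
    t1 = np.full((1, 2), phantom_truth.get("water").t1)
    b1 = np.ones((1, 2))
    mask = np.ones((1, 2), bool)
    cfg = FitConfig(system=phantom_truth, scheme=scheme)
    maps = fit_image(data, t1, b1, mask, cfg, schedule)
    ref = fit_spectrum(clean_z, None, cfg)
    assert maps["semisolid_m0r"][0, 0] == pytest.approx(ref.psr, rel=1e-6)
    assert maps["semisolid_m0r"][0, 0] == maps["semisolid_m0r"][0, 1]
    with pytest.raises(ValueError):
        fit_image(data, t1, b1, np.zeros((1, 2), bool), cfg, schedule)
    with pytest.raises(ValueError):
        fit_image(data[..., :-1], t1, b1, mask, cfg, schedule)
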