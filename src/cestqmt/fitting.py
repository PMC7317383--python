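"""Voxel-wise Bayesian (MAP) estimation of pool parameters from Z-spectra.

Each voxel's normalized Z-spectrum is fit by maximizing a Gaussian
posterior: an additive-Gaussian noise likelihood on the normalized signal
times Gaussian priors on the free parameters.  Positive-valued parameters
(relative pool sizes ``m0r``, exchange rates ``k``, transverse relaxation
times ``T2``) are estimated on the log scale with log-normal priors; the
static field offset B0 is estimated on the linear scale.  Water (and every
pool) T1 is fixed to the observed T1 supplied as a prior, and the relative
transmit field B1 scales both the saturation amplitude and the excitation
flip.  Posterior standard deviations are Laplace approximations from the
Gauss-Newton Hessian at the optimum.

Three multi-pool analysis variants are provided: ``cest_mt`` fits all
pools simultaneously; ``qmt_fix`` first fits water + semisolid on the
|offset| > 5 ppm (qMT) points and then fixes them while fitting the CEST
pools; ``noe_mt`` merges NOE and semisolid into a single mobile pool at
-3.5 ppm.  The derived CEST effect size MTR* is computed from the fitted
(m0r, k) of a pool by simulating idealized one- and two-pool spectra.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .pools import Pool, PoolSystem
from .sequence import AcquisitionSchedule, SaturationScheme
from .signal_model import SteadyStateModel, ZSpectrum

__all__ = [
    "ParameterPrior",
    "FitConfig",
    "PosteriorEstimate",
    "default_priors",
    "fit_spectrum",
    "fit_qmt_fix",
    "fit_image",
    "mtr_star",
    "estimate_t1",
]

LOG10 = math.log(10.0)

#: Idealized relaxation used in the MTR* two-pool simulations (seconds).
MTRSTAR_IDEAL = {
    "water": (1.0, 0.140),
    "amide": (1.0, 0.010),
    "noe": (1.0, 0.005),
}


@dataclass
class ParameterPrior:
    """Gaussian prior on one parameter.

    For ``log_domain`` parameters the prior is log-normal: ``mean`` is in
    natural units but ``sd`` is in log units (``ln(10)`` = one decade).
    ``sd = 0`` fixes the parameter at its mean.
    """

    mean: float
    sd: float
    log_domain: bool = False

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("prior sd must be non-negative")
        if self.log_domain and self.mean <= 0:
            raise ValueError("log-domain priors require a positive mean")


def default_priors(system: PoolSystem) -> dict[tuple[str, str], ParameterPrior]:
    """Weakly-informative priors centred on the template values.

    One decade on ``m0r`` and ``k``, half a decade on ``T2``; pool T1
    values are fixed (no prior entry means not estimated).
    """
    priors: dict[tuple[str, str], ParameterPrior] = {}
    water = system.pools[0]
    priors[("water", "t2")] = ParameterPrior(water.t2, LOG10 / 2, log_domain=True)
    for p in system.pools[1:]:
        priors[(p.name, "m0r")] = ParameterPrior(p.m0r, LOG10, log_domain=True)
        priors[(p.name, "k_to_water")] = ParameterPrior(p.k_to_water, LOG10, log_domain=True)
        priors[(p.name, "t2")] = ParameterPrior(p.t2, LOG10 / 2, log_domain=True)
    return priors


@dataclass
class FitConfig:
    """Everything the fitter needs besides the data.

    ``system`` is the pool template (starting values and fixed parameters);
    ``priors`` maps ``(pool_name, param)`` to priors for the free
    parameters, ``param`` one of ``m0r``, ``k_to_water``, ``t2``.
    """

    system: PoolSystem
    scheme: SaturationScheme
    priors: dict[tuple[str, str], ParameterPrior] = field(default_factory=dict)
    estimate_b0: bool = True
    b0_prior: ParameterPrior = field(default_factory=lambda: ParameterPrior(0.0, 0.1))
    b1_scale: float = 1.0
    noise_sd: float | None = None  # None: estimate from the residuals
    n_starts: int = 3
    seed: int = 0
    max_nfev: int | None = None

    def __post_init__(self) -> None:
        if not self.priors:
            self.priors = default_priors(self.system)

    def with_(self, **kw) -> "FitConfig":
        return replace(self, **kw)


@dataclass
class PosteriorEstimate:
    """Per-parameter posterior means/sds plus fit diagnostics."""

    params: dict[tuple[str, str], tuple[float, float]]
    b0_shift_ppm: float
    b0_sd_ppm: float
    residual_rms: float
    converged: bool
    system: PoolSystem  # template updated with the fitted values

    def value(self, pool: str, param: str) -> float:
        return self.params[(pool, param)][0]

    def sd(self, pool: str, param: str) -> float:
        return self.params[(pool, param)][1]

    @property
    def psr(self) -> float:
        """Semisolid-to-water pool size ratio (fraction)."""
        for p in self.system.semisolid:
            return p.m0r
        raise ValueError("no semisolid pool in this fit")


class _Packer:
    """Maps between the free-parameter vector (estimation domain) and a
    PoolSystem + B0 shift."""

    def __init__(self, config: FitConfig):
        self.config = config
        self.entries = [
            (pool, param, prior)
            for (pool, param), prior in config.priors.items()
            if prior.sd > 0
        ]
        self.n_data_params = len(self.entries) + (1 if config.estimate_b0 else 0)
        if not self.entries and not config.estimate_b0:
            raise ValueError("no free parameters: all priors are fixed")

    def x0(self) -> np.ndarray:
        x = [
            math.log(pr.mean) if pr.log_domain else pr.mean
            for _, _, pr in self.entries
        ]
        if self.config.estimate_b0:
            x.append(self.config.b0_prior.mean)
        return np.array(x)

    def prior_center_scale(self) -> tuple[np.ndarray, np.ndarray]:
        mu, sd = [], []
        for _, _, pr in self.entries:
            mu.append(math.log(pr.mean) if pr.log_domain else pr.mean)
            sd.append(pr.sd)
        if self.config.estimate_b0:
            mu.append(self.config.b0_prior.mean)
            sd.append(self.config.b0_prior.sd if self.config.b0_prior.sd > 0 else np.inf)
        return np.array(mu), np.array(sd)

    def unpack(self, x: np.ndarray) -> tuple[PoolSystem, float]:
        # apply fixed-at-mean priors first, then the free values
        sys_ = self.config.system
        for (pool, param), pr in self.config.priors.items():
            if pr.sd == 0:
                sys_ = sys_.replace_pool(pool, **{param: pr.mean})
        for (pool, param, pr), xi in zip(self.entries, x):
            val = math.exp(xi) if pr.log_domain else xi
            sys_ = sys_.replace_pool(pool, **{param: val})
        b0 = float(x[-1]) if self.config.estimate_b0 else self.config.b0_prior.mean
        return sys_, b0


def _residuals(x, packer, z_values, schedule, sigma, mu, prior_sd):
    config = packer.config
    system, b0 = packer.unpack(x)
    model = SteadyStateModel(system, config.scheme).zspectrum(
        schedule, b0_shift_ppm=b0, b1_scale=config.b1_scale
    )
    data_res = (model.values - z_values) / sigma
    prior_res = (x - mu) / prior_sd
    return np.concatenate([data_res, prior_res])


def fit_spectrum(
    z: ZSpectrum | np.ndarray,
    schedule: AcquisitionSchedule | None,
    config: FitConfig,
) -> PosteriorEstimate:
    """MAP fit of one Z-spectrum.

    ``z`` is a ZSpectrum or an array of normalized values matching
    ``schedule``.  Raises if there are fewer data points than free
    parameters.
    """
    if isinstance(z, ZSpectrum):
        values = z.values
        schedule = z.schedule if schedule is None else schedule
    else:
        values = np.asarray(z, dtype=float)
    if schedule is None:
        raise ValueError("a schedule is required")
    if values.shape != schedule.offsets_ppm.shape:
        raise ValueError("data and schedule sizes differ")

    packer = _Packer(config)
    if len(values) < packer.n_data_params:
        raise ValueError(
            f"{len(values)} data points cannot constrain "
            f"{packer.n_data_params} free parameters"
        )
    mu, prior_sd = packer.prior_center_scale()
    sigma = config.noise_sd if config.noise_sd is not None else 0.01

    rng = np.random.default_rng(config.seed)
    x0 = packer.x0()
    jitter_sd = np.where(np.isfinite(prior_sd), 0.3 * np.minimum(prior_sd, 1.0), 0.0)
    starts = [x0] + [
        x0 + rng.normal(0.0, jitter_sd) for _ in range(max(0, config.n_starts - 1))
    ]

    def solve(x_init, sig):
        return optimize.least_squares(
            _residuals,
            x_init,
            args=(packer, values, schedule, sig, mu, prior_sd),
            method="lm",
            x_scale="jac",
            max_nfev=config.max_nfev,
        )

    best = None
    for x_init in starts:
        try:
            res = solve(x_init, sigma)
        except (ValueError, np.linalg.LinAlgError):
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("all optimization starts failed")

    if config.noise_sd is None:
        # re-estimate the noise level from the data residuals and refit once
        data_res = best.fun[: len(values)] * sigma
        # floor at the reproducibility level of a normalized Z-spectrum so
        # priors are never swamped on (near-)noiseless data
        sigma_hat = max(float(np.std(data_res)), 5e-4)
        best = solve(best.x, sigma_hat)
        sigma = sigma_hat

    system, b0 = packer.unpack(best.x)
    data_res = best.fun[: len(values)] * sigma
    rms = float(np.sqrt(np.mean(data_res**2)))

    # Laplace sds: J already whitened by sigma and prior sds
    J = best.jac
    try:
        cov = np.linalg.inv(J.T @ J)
        x_sd = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        x_sd = np.full(best.x.size, np.nan)

    params: dict[tuple[str, str], tuple[float, float]] = {}
    for i, (pool, param, pr) in enumerate(packer.entries):
        val = getattr(system.get(pool), param)
        sd = val * x_sd[i] if pr.log_domain else x_sd[i]
        params[(pool, param)] = (float(val), float(sd))
    # fixed parameters reported with sd 0
    for (pool, param), pr in config.priors.items():
        if pr.sd == 0:
            params[(pool, param)] = (pr.mean, 0.0)
    b0_sd = float(x_sd[-1]) if config.estimate_b0 else 0.0

    return PosteriorEstimate(
        params=params,
        b0_shift_ppm=b0,
        b0_sd_ppm=b0_sd,
        residual_rms=rms,
        converged=bool(best.status > 0),
        system=system,
    )


def two_pool_config(config: FitConfig) -> FitConfig:
    """Water + semisolid reduction of a fit configuration."""
    keep = {"water"} | {p.name for p in config.system.semisolid}
    drop = [p.name for p in config.system.pools if p.name not in keep]
    sys2 = config.system.without(*drop)
    priors = {
        key: pr for key, pr in config.priors.items() if key[0] in keep
    }
    return config.with_(system=sys2, priors=priors)


def fit_qmt_fix(
    z: ZSpectrum | np.ndarray,
    schedule: AcquisitionSchedule | None,
    config: FitConfig,
) -> tuple[PosteriorEstimate, PosteriorEstimate]:
    """Two-stage analysis: qMT first, CEST with the MT pool fixed.

    Stage 1 fits water + semisolid using only the |offset| > 5 ppm points
    (plus references); stage 2 fixes water and semisolid at the stage-1
    posterior means (prior sd = 0) and fits the CEST pools on the full
    schedule.  Returns (stage1, stage2).
    """
    if isinstance(z, ZSpectrum):
        values = z.values
        schedule = z.schedule if schedule is None else schedule
    else:
        values = np.asarray(z, dtype=float)
    qmt_mask = schedule.is_qmt | schedule.is_reference
    if not np.any(schedule.is_qmt):
        raise ValueError("qMT-fix requires points beyond |offset| = 5 ppm")

    cfg1 = two_pool_config(config).with_(estimate_b0=False)
    stage1 = fit_spectrum(values[qmt_mask], schedule.subset(qmt_mask), cfg1)

    fixed = dict(config.priors)
    sys_ = config.system
    for (pool, param), (val, _sd) in stage1.params.items():
        fixed[(pool, param)] = ParameterPrior(val, 0.0, log_domain=False)
        sys_ = sys_.replace_pool(pool, **{param: val})
    cfg2 = config.with_(system=sys_, priors=fixed)
    stage2 = fit_spectrum(values, schedule, cfg2)
    return stage1, stage2


def fit_image(
    data4d: np.ndarray,
    t1_map: np.ndarray,
    b1_map: np.ndarray,
    mask: np.ndarray,
    config: FitConfig,
    schedule: AcquisitionSchedule,
) -> dict[str, np.ndarray]:
    """Voxel-wise fit of a 4D Z-spectrum stack.

    The last axis of ``data4d`` indexes schedule points (raw signal;
    normalization by the reference volumes happens here).  Water T1 is
    fixed per voxel from ``t1_map``; ``b1_map`` scales the nominal B1.
    Returns maps named ``"<pool>_<param>"`` (+ ``_sd``), ``b0_ppm`` and
    ``residual_rms``; background voxels are NaN.
    """
    spatial = data4d.shape[:-1]
    if data4d.shape[-1] != len(schedule):
        raise ValueError(
            f"{data4d.shape[-1]} volumes but schedule has {len(schedule)} points"
        )
    for name, arr in (("t1_map", t1_map), ("b1_map", b1_map), ("mask", mask)):
        if arr.shape != spatial:
            raise ValueError(f"{name} shape {arr.shape} does not match data {spatial}")
    if not np.any(mask):
        raise ValueError("mask selects no voxels")

    schedule.require_reference()
    ref = schedule.is_reference
    maps: dict[str, np.ndarray] = {}

    def store(key, idx, val):
        if key not in maps:
            maps[key] = np.full(spatial, np.nan)
        maps[key][idx] = val

    for idx in np.argwhere(mask):
        idx = tuple(idx)
        raw = data4d[idx]
        s0 = float(np.mean(raw[ref]))
        if s0 <= 0:
            continue
        cfg = config.with_(
            system=config.system.replace_pool("water", t1=float(t1_map[idx])),
            b1_scale=float(b1_map[idx]),
        )
        est = fit_spectrum(raw / s0, schedule, cfg)
        for (pool, param), (val, sd) in est.params.items():
            store(f"{pool}_{param}", idx, val)
            store(f"{pool}_{param}_sd", idx, sd)
        store("b0_ppm", idx, est.b0_shift_ppm)
        store("residual_rms", idx, est.residual_rms)
    return maps


def mtr_star(
    m0r: float,
    k_to_water: float,
    scheme: SaturationScheme,
    shift_ppm: float,
    pool_kind: str = "amide",
    sat_flip_deg: float | None = None,
    center_freq_mhz: float = 127.7,
    ideal_t1_t2: tuple[float, float] | None = None,
) -> float:
    """Model-derived CEST effect size MTR*, in percent.

    Simulates an idealized two-pool spectrum (water + the target pool with
    the supplied ``m0r`` and exchange rate, idealized relaxation: water
    T1 = 1.0 s / T2 = 140 ms, amide T1 = 1 s / T2 = 10 ms, NOE T1 = 1 s /
    T2 = 5 ms) and a one-pool water spectrum under the same scheme, and
    returns their difference at the pool offset normalized by the
    unsaturated signal.
    """
    if m0r < 0 or k_to_water < 0:
        raise ValueError("m0r and k must be non-negative")
    wt1, wt2 = MTRSTAR_IDEAL["water"]
    pt1, pt2 = ideal_t1_t2 if ideal_t1_t2 is not None else MTRSTAR_IDEAL[pool_kind]
    water = Pool("water", 0.0, wt1, wt2, 1.0)
    sched = AcquisitionSchedule(
        np.array([shift_ppm, 800.0]),
        np.full(2, scheme.sat_flip_deg if sat_flip_deg is None else sat_flip_deg),
    )
    one = PoolSystem([water], center_freq_mhz)
    z_w = SteadyStateModel(one, scheme).zspectrum(sched).values[0]
    if m0r == 0.0:
        return 0.0
    target = Pool(pool_kind, shift_ppm, pt1, pt2, m0r, k_to_water)
    two = PoolSystem([water, target], center_freq_mhz)
    z_fs = SteadyStateModel(two, scheme).zspectrum(sched).values[0]
    return float(100.0 * (z_w - z_fs))


def estimate_t1(signals, timing, mode: str = "ir", tr: float | None = None):
    """T1 from inversion-recovery or variable-flip-angle data.

    ``mode="ir"``: ``signals`` are magnitudes at inversion times ``timing``
    (s); fits ``|a (1 - 2 exp(-TI/T1))|``.  ``mode="vfa"``: ``signals`` are
    spoiled-gradient-echo signals at flip angles ``timing`` (degrees) with
    repetition time ``tr`` (s).  Returns (t1, amplitude).
    """
    y = np.asarray(signals, dtype=float)
    t = np.asarray(timing, dtype=float)
    if y.size != t.size or y.size < 3:
        raise ValueError("need at least 3 matched samples")

    if mode == "ir":
        def model(x):
            a, logt1 = x
            return np.abs(a * (1.0 - 2.0 * np.exp(-t / np.exp(logt1)))) - y

        x0 = np.array([float(np.max(y)), math.log(max(np.median(t), 1e-3))])
        res = optimize.least_squares(model, x0, method="lm")
        return float(np.exp(res.x[1])), float(res.x[0])
    if mode == "vfa":
        if tr is None:
            raise ValueError("vfa mode requires tr")
        rad = np.deg2rad(t)

        def model(x):
            a, logt1 = x
            e = np.exp(-tr / np.exp(logt1))
            return a * np.sin(rad) * (1 - e) / (1 - e * np.cos(rad)) - y

        x0 = np.array([float(np.max(y)) * 10.0, math.log(1.0)])
        res = optimize.least_squares(model, x0, method="lm")
        return float(np.exp(res.x[1])), float(res.x[0])
    raise ValueError(f"unknown mode {mode!r}")
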