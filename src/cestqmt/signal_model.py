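"""Steady-state signal model for pulsed multi-pool CEST/MT sequences.

The coupled Bloch-McConnell equations for N exchanging pools are linear,
``dM/dt = (R_L + W) M - R_L M0``, where ``R_L`` collects relaxation and
water-centric exchange and ``W`` the RF terms (precession and nutation for
mobile pools, a lineshape-derived saturation rate for semisolid pools).
With the shaped saturation train reduced to its continuous-wave equivalent
pulse (CWEP), each shot of the sequence is a composition of affine maps --
saturation (t_m), spoiling, a free-precession gap (t_s), an instantaneous
excitation rotation, and the readout/recovery gap (t_r) -- and the periodic
steady state is the fixed point of that composition, solved directly as a
linear system.  The reported signal is the water longitudinal magnetization
immediately before excitation, normalized by its value at a far
off-resonance reference offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .lineshapes import rf_absorption_rate
from .pools import MOBILE, Pool, PoolSystem
from .sequence import AcquisitionSchedule, SaturationScheme

__all__ = [
    "ZSpectrum",
    "SteadyStateModel",
    "build_relaxation_matrix",
    "build_saturation_matrix",
    "steady_state_magnetization",
    "simulate_zspectrum",
]


@dataclass
class ZSpectrum:
    """Normalized signals indexed by (offset ppm, saturation flip)."""

    schedule: AcquisitionSchedule
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.schedule.offsets_ppm.shape:
            raise ValueError("values must match the schedule point-for-point")

    @property
    def offsets_ppm(self) -> np.ndarray:
        return self.schedule.offsets_ppm


def build_relaxation_matrix(system: PoolSystem) -> np.ndarray:
    """Relaxation/exchange matrix R_L over the stacked state vector.

    Water transverse rows couple to mobile solutes only (semisolid pools
    have no transverse state); all z rows carry the water-centric exchange
    with detailed balance k_water->s = k_s->water * m0r_s.
    """
    n = system.dim
    R = np.zeros((n, n))
    water = system.pools[0]
    wx, wy = system.xy_index(water)
    wz = system.z_index(water)

    k_fs_xy = 0.0  # water transverse loss: mobile solutes only
    k_fs_z = 0.0
    for p in system.pools[1:]:
        k_fs = p.k_to_water * p.m0r
        k_fs_z += k_fs
        iz = system.z_index(p)
        if p.klass == MOBILE:
            k_fs_xy += k_fs
            ix, iy = system.xy_index(p)
            R[ix, ix] = R[iy, iy] = -p.r2 - p.k_to_water
            R[ix, wx] = R[iy, wy] = k_fs
            R[wx, ix] = R[wy, iy] = p.k_to_water
        R[iz, iz] = -p.r1 - p.k_to_water
        R[iz, wz] = k_fs
        R[wz, iz] = p.k_to_water

    R[wx, wx] += -water.r2 - k_fs_xy
    R[wy, wy] += -water.r2 - k_fs_xy
    R[wz, wz] += -water.r1 - k_fs_z
    return R


def build_saturation_matrix(
    system: PoolSystem, offset_ppm: float, omega1: float
) -> np.ndarray:
    """RF matrix W at a given offset (ppm) and CWEP amplitude (rad/s).

    Mobile pools get a 2*pi*Delta precession block (Delta = offset minus
    the pool shift, in Hz) with +-omega1 y<->z nutation; each semisolid
    pool gets its lineshape saturation rate on the diagonal.
    """
    if omega1 < 0:
        raise ValueError("omega1 must be non-negative")
    n = system.dim
    W = np.zeros((n, n))
    for p in system.mobile:
        ix, iy = system.xy_index(p)
        iz = system.z_index(p)
        omega = 2.0 * np.pi * system.ppm_to_hz(offset_ppm - p.shift_ppm)
        W[ix, iy] = omega
        W[iy, ix] = -omega
        W[iy, iz] = -omega1
        W[iz, iy] = omega1
    for p in system.semisolid:
        iz = system.z_index(p)
        delta_hz = system.ppm_to_hz(offset_ppm - p.shift_ppm)
        W[iz, iz] = -rf_absorption_rate(omega1, delta_hz, p.t2, p.lineshape)
    return W


def _spoil_matrix(system: PoolSystem) -> np.ndarray:
    s = np.ones(system.dim)
    for p in system.mobile:
        ix, iy = system.xy_index(p)
        s[ix] = s[iy] = 0.0
    return np.diag(s)


def _excitation_matrix(system: PoolSystem, flip_deg: float) -> np.ndarray:
    """Instantaneous on-resonance excitation: sin(a) on transverse, cos(a)
    on every longitudinal component (semisolid included)."""
    a = np.deg2rad(flip_deg)
    c = np.ones(system.dim)
    for p in system.mobile:
        ix, iy = system.xy_index(p)
        c[ix] = c[iy] = np.sin(a)
    for p in system.pools:
        c[system.z_index(p)] = np.cos(a)
    return np.diag(c)


class SteadyStateModel:
    """Closed-form pulsed steady state for one pool system and scheme.

    Caches the saturation-independent propagators (spoil, excitation, the
    t_s and t_r interval maps); per offset only the saturation-interval
    propagator is rebuilt.
    """

    def __init__(self, system: PoolSystem, scheme: SaturationScheme):
        self.system = system
        self.scheme = scheme
        self.r_l = build_relaxation_matrix(system)
        self.m0 = system.m0_vec()
        self._e_s = expm(self.r_l * scheme.t_s)
        self._e_r = expm(self.r_l * scheme.t_r)
        self._spoil = _spoil_matrix(system)
        self._wz = system.z_index(system.pools[0])

    def pre_excitation_state(
        self,
        offset_ppm: float,
        omega1: float,
        exc_flip_deg: float | None = None,
    ) -> np.ndarray:
        """State vector immediately before the excitation pulse at the
        periodic steady state of the shot cycle."""
        sys_, sch = self.system, self.scheme
        exc = sch.exc_flip_deg if exc_flip_deg is None else exc_flip_deg
        A_sat = self.r_l + build_saturation_matrix(sys_, offset_ppm, omega1)
        try:
            m_ss = np.linalg.solve(A_sat, self.r_l @ self.m0)
        except np.linalg.LinAlgError as err:
            raise ValueError("degenerate saturation parameters (singular R_L + W)") from err
        e_m = expm(A_sat * sch.t_m)

        S, C = self._spoil, _excitation_matrix(sys_, exc)
        # affine composition of one full cycle starting just before saturation
        A = e_m
        c = (np.eye(sys_.dim) - e_m) @ m_ss
        A, c = S @ A, S @ c  # spoil
        A, c = self._e_s @ A, self._e_s @ (c - self.m0) + self.m0  # t_s
        pre_exc = (A.copy(), c.copy())
        A, c = C @ S @ A, C @ S @ c  # spoil + excite
        A, c = self._e_r @ A, self._e_r @ (c - self.m0) + self.m0  # t_r
        A, c = S @ A, S @ c
        try:
            m_star = np.linalg.solve(np.eye(sys_.dim) - A, c)
        except np.linalg.LinAlgError as err:
            raise ValueError("non-convergent sequence configuration") from err
        return pre_exc[0] @ m_star + pre_exc[1]

    def water_z(self, offset_ppm, omega1, exc_flip_deg=None) -> float:
        return float(
            self.pre_excitation_state(offset_ppm, omega1, exc_flip_deg)[self._wz]
        )

    def zspectrum(
        self,
        schedule: AcquisitionSchedule,
        b0_shift_ppm: float = 0.0,
        b1_scale: float = 1.0,
        s0: float | None = None,
    ) -> ZSpectrum:
        """Simulate the normalized Z-spectrum over a schedule.

        ``b0_shift_ppm`` shifts the water resonance: the effective RF
        offset becomes ``offset - b0``.  ``b1_scale`` multiplies both the
        saturation amplitude and the excitation flip.  ``s0`` overrides
        reference normalization when the schedule lacks reference points.
        """
        exc = self.scheme.exc_flip_deg * b1_scale
        sig = np.empty(len(schedule))
        cache: dict[tuple[float, float], float] = {}
        for i, (off, flip) in enumerate(
            zip(schedule.offsets_ppm, schedule.sat_flips_deg)
        ):
            key = (off, flip)
            if key not in cache:
                omega1 = self.scheme.cwep_omega1(flip) * b1_scale
                cache[key] = self.water_z(off - b0_shift_ppm, omega1, exc)
            sig[i] = cache[key]
        if s0 is None:
            schedule.require_reference()
            s0 = float(np.mean(sig[schedule.is_reference]))
        return ZSpectrum(schedule, sig / s0)


# -- thin functional wrappers -------------------------------------------


def steady_state_magnetization(
    system: PoolSystem,
    scheme: SaturationScheme,
    offset_ppm: float,
    omega1: float,
    exc_flip_deg: float | None = None,
) -> np.ndarray:
    return SteadyStateModel(system, scheme).pre_excitation_state(
        offset_ppm, omega1, exc_flip_deg
    )


def simulate_zspectrum(
    system: PoolSystem,
    scheme: SaturationScheme,
    schedule: AcquisitionSchedule,
    b0_shift_ppm: float = 0.0,
    b1_scale: float = 1.0,
    s0: float | None = None,
) -> ZSpectrum:
    return SteadyStateModel(system, scheme).zspectrum(schedule, b0_shift_ppm, b1_scale, s0)
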