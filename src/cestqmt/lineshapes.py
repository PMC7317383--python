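"""Absorption lineshapes for the semisolid pool.

The semisolid (macromolecular) pool has no resolvable transverse
magnetization; its response to off-resonance RF is described by an
absorption lineshape ``g(Delta, T2)`` with units of seconds, normalized so
that the integral over angular frequency (``2*pi*Delta``) is one.  The RF
saturation rate it induces is ``pi * omega1**2 * g`` (rad/s amplitude
``omega1 = gamma*B1``), which enters the longitudinal Bloch equation of the
semisolid pool directly.

Three standard shapes are provided:

``lorentzian``
    g = (T2/pi) / (1 + (2*pi*Delta*T2)**2) — liquids and mobile pools.
``gaussian``
    g = T2/sqrt(2*pi) * exp(-(2*pi*Delta*T2)**2 / 2) — gels such as agarose.
``super_lorentzian``
    Orientation average of a Gaussian over the dipolar angle, appropriate
    for semisolids in tissue.  It diverges on resonance; near-resonance
    values are obtained by cubic extrapolation from just outside a cutoff
    (1 kHz by default), the standard practice in qMT fitting.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "LINESHAPES",
    "lineshape_value",
    "rf_absorption_rate",
    "SUPER_LORENTZIAN_CUTOFF_HZ",
]

LINESHAPES = ("lorentzian", "gaussian", "super_lorentzian")

#: On-resonance singularity cutoff for the super-Lorentzian (Hz); values at
#: |Delta| below this are cubic-extrapolated from [cutoff, 1.5*cutoff].
SUPER_LORENTZIAN_CUTOFF_HZ = 1000.0

# 512-point Gauss-Legendre rule on theta in [0, pi/2], computed once.
_GL_X, _GL_W = np.polynomial.legendre.leggauss(512)
_SL_THETA = 0.25 * np.pi * (_GL_X + 1.0)
_SL_WEIGHT = 0.25 * np.pi * _GL_W


def _super_lorentzian_raw(delta_hz: np.ndarray, t2: float) -> np.ndarray:
    """Bare angular integral; diverges as |delta| -> 0."""
    c = 3.0 * np.cos(_SL_THETA) ** 2 - 1.0  # (512,)
    x = 2.0 * np.pi * np.atleast_1d(delta_hz)[:, None] * t2 / c[None, :]
    integrand = (
        np.sin(_SL_THETA)[None, :]
        * np.sqrt(2.0 / np.pi)
        * (t2 / np.abs(c))[None, :]
        * np.exp(-2.0 * x**2)
    )
    return integrand @ _SL_WEIGHT


def lineshape_value(
    kind: str,
    delta_hz,
    t2: float,
    *,
    sl_cutoff_hz: float = SUPER_LORENTZIAN_CUTOFF_HZ,
):
    """Absorption lineshape g(Delta, T2) in seconds.

    Parameters
    ----------
    kind : {"lorentzian", "gaussian", "super_lorentzian"}
    delta_hz : float or array
        Frequency offset from the pool's resonance, in Hz.
    t2 : float
        Transverse relaxation time of the pool, in seconds (> 0).
    sl_cutoff_hz : float, optional
        Near-resonance cutoff for the super-Lorentzian.
    """
    if t2 <= 0:
        raise ValueError(f"t2 must be positive, got {t2!r}")
    delta = np.asarray(delta_hz, dtype=float)
    if not np.all(np.isfinite(delta)):
        raise ValueError("delta must be finite")
    scalar = delta.ndim == 0
    delta = np.atleast_1d(delta)

    if kind == "lorentzian":
        out = (t2 / np.pi) / (1.0 + (2.0 * np.pi * delta * t2) ** 2)
    elif kind == "gaussian":
        out = t2 / np.sqrt(2.0 * np.pi) * np.exp(-0.5 * (2.0 * np.pi * delta * t2) ** 2)
    elif kind == "super_lorentzian":
        out = _super_lorentzian_raw(delta, t2)
        inside = np.abs(delta) < sl_cutoff_hz
        if np.any(inside):
            # cubic in |delta| anchored just outside the cutoff
            anchors = np.linspace(sl_cutoff_hz, 1.5 * sl_cutoff_hz, 4)
            coeffs = np.polyfit(anchors, _super_lorentzian_raw(anchors, t2), 3)
            out = np.where(inside, np.polyval(coeffs, np.abs(delta)), out)
    else:
        raise ValueError(f"unknown lineshape kind {kind!r}")
    return float(out[0]) if scalar else out


def rf_absorption_rate(
    omega1: float,
    delta_hz,
    t2m: float,
    kind: str,
    *,
    sl_cutoff_hz: float = SUPER_LORENTZIAN_CUTOFF_HZ,
):
    """Semisolid saturation rate ``pi * omega1**2 * g(Delta, T2M)`` in 1/s.

    ``omega1 = gamma * B1`` is the RF amplitude in rad/s; the rate is
    quadratic in B1 and zero when the RF is off.
    """
    if omega1 < 0:
        raise ValueError("omega1 must be non-negative")
    if omega1 == 0.0:
        return np.zeros_like(np.asarray(delta_hz, dtype=float)) if np.ndim(delta_hz) else 0.0
    g = lineshape_value(kind, delta_hz, t2m, sl_cutoff_hz=sl_cutoff_hz)
    return np.pi * omega1**2 * g
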