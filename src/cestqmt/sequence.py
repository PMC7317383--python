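"""Saturation schemes, acquisition schedules and the CWEP reduction.

A pulsed CEST shot consists of a saturation pulse train (duration ``t_m``),
a spoiled free-precession gap (``t_s``), an on-resonance excitation pulse
(flip ``exc_flip_deg``, treated as instantaneous with its duration folded
into the readout interval), and the readout/recovery gap (``t_r``).  The
shaped pulse train is reduced to a continuous-wave equivalent pulse (CWEP)
with the same mean-square amplitude (average power) over the train,
including inter-pulse gaps; an average-amplitude alternative is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf

__all__ = ["SaturationScheme", "AcquisitionSchedule", "cwep_omega1"]

#: Gaussian pulse shape: truncated at +-3 sigma, i.e. sigma = duration / 6.
_GAUSS_TRUNC_SIGMA = 3.0


@dataclass
class SaturationScheme:
    """Pulse-train description for one pulsed-saturation shot.

    Defaults mirror a 3 T protocol: fifty 20-ms Gaussian pulses at 50% duty
    cycle (2 s of saturation), 7 deg excitation, 2.375 s shot-to-shot
    interval.
    """

    n_pulses: int = 50
    pulse_dur: float = 0.020  # s
    duty_cycle: float = 0.5
    pulse_shape: str = "gaussian"  # or "block"
    sat_flip_deg: float = 184.0  # per-pulse flip angle
    exc_flip_deg: float = 7.0
    shot_interval: float = 2.375  # s
    t_s: float = 0.010  # spoil / free-precession gap after saturation, s

    def __post_init__(self) -> None:
        if self.pulse_dur <= 0:
            raise ValueError("pulse duration must be positive")
        if not 0.0 < self.duty_cycle <= 1.0:
            raise ValueError("duty cycle must be in (0, 1]")
        if self.pulse_shape not in ("gaussian", "block"):
            raise ValueError(f"unknown pulse shape {self.pulse_shape!r}")
        if self.t_m + self.t_s > self.shot_interval:
            raise ValueError("saturation train longer than shot interval")

    @property
    def t_m(self) -> float:
        """Total saturation-train duration (pulses plus gaps), s."""
        return self.n_pulses * self.pulse_dur / self.duty_cycle

    @property
    def t_r(self) -> float:
        """Readout + recovery interval (excitation treated as instant), s."""
        return self.shot_interval - self.t_m - self.t_s

    # -- pulse waveform ---------------------------------------------------
    def _shape_integrals(self) -> tuple[float, float]:
        """(integral of s(t) dt, integral of s(t)^2 dt) over one pulse,
        for the unit-peak shape s(t)."""
        tp = self.pulse_dur
        if self.pulse_shape == "block":
            return tp, tp
        sigma = tp / (2.0 * _GAUSS_TRUNC_SIGMA)
        a1 = sigma * np.sqrt(2.0 * np.pi) * erf(tp / (2.0 * np.sqrt(2.0) * sigma))
        a2 = sigma * np.sqrt(np.pi) * erf(tp / (2.0 * sigma))
        return float(a1), float(a2)

    def omega1_peak(self, sat_flip_deg: float | None = None) -> float:
        """Peak RF amplitude (rad/s) delivering the per-pulse flip angle."""
        flip = np.deg2rad(self.sat_flip_deg if sat_flip_deg is None else sat_flip_deg)
        a1, _ = self._shape_integrals()
        return float(flip / a1)

    def pulse_waveform(self, n_samples: int, sat_flip_deg: float | None = None) -> np.ndarray:
        """omega1(t) sampled at n_samples midpoints across one pulse."""
        tp = self.pulse_dur
        t = (np.arange(n_samples) + 0.5) * tp / n_samples
        peak = self.omega1_peak(sat_flip_deg)
        if self.pulse_shape == "block":
            return np.full(n_samples, peak)
        sigma = tp / (2.0 * _GAUSS_TRUNC_SIGMA)
        return peak * np.exp(-0.5 * ((t - tp / 2.0) / sigma) ** 2)

    def cwep_omega1(self, sat_flip_deg: float | None = None, mode: str = "power") -> float:
        """Continuous-wave-equivalent amplitude (rad/s) over ``t_m``.

        ``mode="power"`` (default) matches the mean-square amplitude of the
        train including gaps; ``mode="amplitude"`` matches the mean
        amplitude.  For a block pulse at 100% duty both equal the nominal
        amplitude.
        """
        a1, a2 = self._shape_integrals()
        peak = self.omega1_peak(sat_flip_deg)
        period = self.pulse_dur / self.duty_cycle
        if mode == "power":
            return float(peak * np.sqrt(a2 / period))
        if mode == "amplitude":
            return float(peak * a1 / period)
        raise ValueError(f"unknown CWEP mode {mode!r}")


def cwep_omega1(scheme: SaturationScheme, sat_flip_deg: float | None = None) -> float:
    """Module-level convenience wrapper around SaturationScheme.cwep_omega1."""
    return scheme.cwep_omega1(sat_flip_deg)


@dataclass
class AcquisitionSchedule:
    """Offsets (ppm) and per-point saturation flip angles.

    Points with ``|offset| >= ref_threshold_ppm`` (800 ppm by convention)
    are treated as unsaturated reference (S0) volumes.
    """

    offsets_ppm: np.ndarray
    sat_flips_deg: np.ndarray
    ref_threshold_ppm: float = 800.0

    def __post_init__(self) -> None:
        self.offsets_ppm = np.asarray(self.offsets_ppm, dtype=float)
        self.sat_flips_deg = np.asarray(self.sat_flips_deg, dtype=float)
        if self.offsets_ppm.shape != self.sat_flips_deg.shape:
            raise ValueError("offsets and flips must have matching shapes")
        if self.offsets_ppm.size == 0:
            raise ValueError("schedule must contain at least one point")
        if not np.all(np.isfinite(self.offsets_ppm)):
            raise ValueError("offsets must be finite")

    def __len__(self) -> int:
        return self.offsets_ppm.size

    @property
    def is_reference(self) -> np.ndarray:
        return np.abs(self.offsets_ppm) >= self.ref_threshold_ppm

    @property
    def is_cest(self) -> np.ndarray:
        """CEST region: |offset| <= 5 ppm (qMT region lies beyond)."""
        return np.abs(self.offsets_ppm) <= 5.0

    @property
    def is_qmt(self) -> np.ndarray:
        return (~self.is_cest) & (~self.is_reference)

    def subset(self, mask) -> "AcquisitionSchedule":
        mask = np.asarray(mask)
        return AcquisitionSchedule(
            self.offsets_ppm[mask], self.sat_flips_deg[mask], self.ref_threshold_ppm
        )

    def require_reference(self) -> None:
        if not np.any(self.is_reference):
            raise ValueError("schedule contains no reference (S0) point")
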