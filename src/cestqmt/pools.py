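"""Pool and pool-system containers for multi-pool CEST/MT modelling.

A *pool* is one exchanging proton population.  Mobile pools (water, amide,
NOE, ...) carry full (x, y, z) magnetization; semisolid pools carry only a
longitudinal component plus an absorption lineshape.  Exchange topology is
water-centric: every solute exchanges with water only, with detailed
balance ``k_water->s = k_s->water * m0r_s`` (all magnetizations normalized
to the water equilibrium magnetization, so water has ``m0r = 1``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from .lineshapes import LINESHAPES

__all__ = ["Pool", "PoolSystem", "MOBILE", "SEMISOLID"]

MOBILE = "mobile"
SEMISOLID = "semisolid"


@dataclass
class Pool:
    """One exchanging proton population.

    Parameters
    ----------
    name : str
        Label, e.g. ``"water"``, ``"amide"``.
    shift_ppm : float
        Chemical shift relative to water; positive downfield (amide +3.5,
        NOE -3.5).
    t1, t2 : float
        Longitudinal / transverse relaxation times in seconds.
    m0r : float
        Equilibrium magnetization relative to water (water = 1).  For the
        semisolid pool this is the pool size ratio (PSR).
    k_to_water : float
        Exchange rate from this pool to water in 1/s (k_SF or k_MF);
        zero for water itself.
    klass : {"mobile", "semisolid"}
    lineshape : str or None
        Absorption lineshape kind; semisolid pools only.
    """

    name: str
    shift_ppm: float
    t1: float
    t2: float
    m0r: float
    k_to_water: float = 0.0
    klass: str = MOBILE
    lineshape: str | None = None

    def __post_init__(self) -> None:
        if self.t1 <= 0 or self.t2 <= 0:
            raise ValueError(f"pool {self.name!r}: relaxation times must be positive")
        if self.m0r < 0:
            raise ValueError(f"pool {self.name!r}: m0r must be non-negative")
        if self.k_to_water < 0:
            raise ValueError(f"pool {self.name!r}: exchange rate must be non-negative")
        if self.klass not in (MOBILE, SEMISOLID):
            raise ValueError(f"pool {self.name!r}: unknown class {self.klass!r}")
        if self.klass == SEMISOLID:
            if self.lineshape not in LINESHAPES:
                raise ValueError(
                    f"semisolid pool {self.name!r} needs a lineshape from {LINESHAPES}"
                )
        elif self.lineshape is not None:
            raise ValueError(f"mobile pool {self.name!r} must not carry a lineshape")

    @property
    def r1(self) -> float:
        return 1.0 / self.t1

    @property
    def r2(self) -> float:
        return 1.0 / self.t2

    def with_(self, **kw) -> "Pool":
        return replace(self, **kw)


@dataclass
class PoolSystem:
    """Water plus solute/semisolid pools with water-centric exchange.

    The state vector stacks (x, y, z) for each mobile pool in order,
    followed by one z component per semisolid pool; water is always the
    first pool.
    """

    pools: list[Pool]
    center_freq_mhz: float = 127.7  # 3 T proton frequency; ppm -> Hz scale

    def __post_init__(self) -> None:
        waters = [p for p in self.pools if p.name == "water"]
        if len(waters) != 1 or self.pools[0].name != "water":
            raise ValueError("exactly one water pool required, listed first")
        w = self.pools[0]
        if w.klass != MOBILE or w.shift_ppm != 0 or w.m0r != 1 or w.k_to_water != 0:
            raise ValueError("water pool must be mobile with shift 0, m0r 1, k 0")
        # mobile pools first in state vector, semisolids appended
        self._mobile = [p for p in self.pools if p.klass == MOBILE]
        self._semisolid = [p for p in self.pools if p.klass == SEMISOLID]

    @property
    def mobile(self) -> list[Pool]:
        return self._mobile

    @property
    def semisolid(self) -> list[Pool]:
        return self._semisolid

    @property
    def dim(self) -> int:
        return 3 * len(self._mobile) + len(self._semisolid)

    def z_index(self, pool: Pool) -> int:
        """Row of the pool's longitudinal component in the state vector."""
        if pool.klass == MOBILE:
            return 3 * self._mobile.index(pool) + 2
        return 3 * len(self._mobile) + self._semisolid.index(pool)

    def xy_index(self, pool: Pool) -> tuple[int, int]:
        if pool.klass != MOBILE:
            raise ValueError("semisolid pools have no transverse components")
        i = 3 * self._mobile.index(pool)
        return i, i + 1

    def m0_vec(self) -> np.ndarray:
        """Equilibrium state vector (0, 0, 1, ..., m0r_s, ..., m0r_m)."""
        m0 = np.zeros(self.dim)
        for p in self.pools:
            m0[self.z_index(p)] = p.m0r
        return m0

    def ppm_to_hz(self, ppm) -> np.ndarray | float:
        return np.asarray(ppm, dtype=float) * self.center_freq_mhz

    def get(self, name: str) -> Pool:
        for p in self.pools:
            if p.name == name:
                return p
        raise KeyError(name)

    def without(self, *names: str) -> "PoolSystem":
        return PoolSystem(
            [p for p in self.pools if p.name not in names], self.center_freq_mhz
        )

    def replace_pool(self, name: str, **kw) -> "PoolSystem":
        pools = [p.with_(**kw) if p.name == name else p for p in self.pools]
        return PoolSystem(pools, self.center_freq_mhz)

    def __iter__(self) -> Iterator[Pool]:
        return iter(self.pools)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        out = {"center_freq_mhz": self.center_freq_mhz, "pools": []}
        for p in self.pools:
            d = {
                "name": p.name,
                "shift_ppm": p.shift_ppm,
                "t1": p.t1,
                "t2": p.t2,
                "m0r": p.m0r,
                "k_to_water": p.k_to_water,
                "klass": p.klass,
            }
            if p.lineshape is not None:
                d["lineshape"] = p.lineshape
            out["pools"].append(d)
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "PoolSystem":
        pools = [Pool(**pd) for pd in d["pools"]]
        return cls(pools, center_freq_mhz=d.get("center_freq_mhz", 127.7))
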