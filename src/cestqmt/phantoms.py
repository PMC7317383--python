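"""Digital phantoms and synthetic Z-spectrum data.

Provides the pool-system templates used throughout the package:

``brain_7pool``
    White-matter-like system of water, amide (+3.5 ppm), creatine
    guanidinium (+2.0 ppm, fast exchange), three pools spanning the
    aliphatic NOE-relayed band (-1.75, -2.5, -3.5 ppm) and a
    super-Lorentzian semisolid pool with a 20% pool size ratio.  Shifts,
    exchange rates and T2 values are standard literature conventions; the
    amide fraction is set so that the idealized two-pool amide effect size
    (MTR*) under the reference pulsed scheme is 11.0%, a representative
    white-matter amide effect.
``brain_5pool_hydroxyl``
    The four-pool system (water, amide, NOE, semisolid) plus a
    fast-exchanging hydroxyl pool (+1.0 ppm, 2000 1/s).
``bsa_agarose``
    Protein/gel tube model: BSA concentration (% w/v) maps linearly onto
    amide and NOE pool fractions, agarose concentration onto a
    Gaussian-lineshape semisolid fraction and onto water relaxation.  The
    calibration is a synthetic convention (chosen so 9% BSA matches the
    brain amide fraction), not a measured one; what matters for the
    experiments is that the maps are monotone with known ground truth.

Tube-grid phantom images are generated voxel-wise from the steady-state
model with optional smooth B0/B1 field inhomogeneities and additive
Gaussian noise on the normalized signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pools import Pool, PoolSystem
from .sequence import AcquisitionSchedule, SaturationScheme
from .signal_model import SteadyStateModel

__all__ = [
    "AMIDE_M0R_BRAIN",
    "PhantomLayout",
    "ConcentrationMap",
    "make_pool_system",
    "bsa_series_layout",
    "agarose_series_layout",
    "generate_phantom_image",
    "generate_field_maps",
    "sim_schedule",
    "invivo_schedule",
]

#: Brain amide pool fraction; gives an idealized amide MTR* of 11.0% at
#: the reference scheme (50x20 ms Gaussian pulses, 50% duty, 180 deg).
AMIDE_M0R_BRAIN = 0.005302

_BRAIN_WATER = dict(t1=1.0, t2=0.070)


def _brain_pools(names: tuple[str, ...]) -> list[Pool]:
    catalog = {
        "water": Pool("water", 0.0, m0r=1.0, **_BRAIN_WATER),
        "amide": Pool("amide", 3.5, 1.0, 0.010, AMIDE_M0R_BRAIN, 30.0),
        "creatine": Pool("creatine", 2.0, 1.0, 0.010, 0.001, 1000.0),
        "hydroxyl": Pool("hydroxyl", 1.0, 1.0, 0.005, 0.003, 2000.0),
        "noe1": Pool("noe1", -1.75, 1.0, 0.002, 0.005, 20.0),
        "noe2": Pool("noe2", -2.5, 1.0, 0.002, 0.005, 20.0),
        "noe": Pool("noe", -3.5, 1.0, 0.002, 0.005, 20.0),
        # the macromolecular line in tissue is displaced upfield of water
        "semisolid": Pool(
            "semisolid", -2.34, 1.0, 10e-6, 0.20, 20.0,
            klass="semisolid", lineshape="super_lorentzian",
        ),
    }
    return [catalog[n] for n in names]


@dataclass
class ConcentrationMap:
    """Linear % w/v -> pool-fraction calibration (synthetic convention).

    All maps are monotone and vanish at zero concentration.
    """

    amide_per_bsa: float = AMIDE_M0R_BRAIN / 9.0
    noe_per_bsa: float = 1.5 * AMIDE_M0R_BRAIN / 9.0
    semisolid_per_agarose: float = 0.03
    # water relaxation rates (1/s) as affine functions of concentration
    r1_base: float = 0.33
    r1_per_bsa: float = 0.03
    r1_per_agarose: float = 0.10
    r2_base: float = 0.5
    r2_per_bsa: float = 0.5
    r2_per_agarose: float = 2.0


def make_pool_system(
    template: str,
    conc: tuple[float, float] | None = None,
    conc_map: ConcentrationMap | None = None,
    center_freq_mhz: float = 127.7,
) -> PoolSystem:
    """Build a pool system from a named template.

    ``conc`` is the (BSA % w/v, agarose % w/v) pair for the
    ``bsa_agarose`` template and is ignored by the brain templates.
    """
    if template == "brain_7pool":
        pools = _brain_pools(
            ("water", "amide", "creatine", "noe1", "noe2", "noe", "semisolid")
        )
        return PoolSystem(pools, center_freq_mhz)
    if template == "brain_5pool_hydroxyl":
        pools = _brain_pools(("water", "amide", "hydroxyl", "noe", "semisolid"))
        return PoolSystem(pools, center_freq_mhz)
    if template == "bsa_agarose":
        bsa, agarose = conc if conc is not None else (6.0, 0.65)
        if bsa < 0 or agarose < 0:
            raise ValueError("concentrations must be non-negative")
        cm = conc_map or ConcentrationMap()
        r1 = cm.r1_base + cm.r1_per_bsa * bsa + cm.r1_per_agarose * agarose
        r2 = cm.r2_base + cm.r2_per_bsa * bsa + cm.r2_per_agarose * agarose
        pools = [
            Pool("water", 0.0, 1.0 / r1, 1.0 / r2, 1.0),
            Pool("amide", 3.5, 1.0, 0.010, cm.amide_per_bsa * bsa, 30.0),
            Pool("noe", -3.5, 1.0, 0.005, cm.noe_per_bsa * bsa, 20.0),
            Pool(
                "semisolid", 0.0, 1.0, 10e-6, cm.semisolid_per_agarose * agarose,
                50.0, klass="semisolid", lineshape="gaussian",
            ),
        ]
        return PoolSystem(pools, center_freq_mhz)
    raise ValueError(f"unknown template {template!r}")


# -- acquisition schedules ----------------------------------------------


def sim_schedule(ref_ppm: float = 800.0) -> AcquisitionSchedule:
    """Simulation schedule: 36 uniform offsets over +-5 ppm at 180 deg,
    MT offsets {7.5, 15, 30, 60, 100} ppm at 180 and 540 deg, plus a
    reference point per power."""
    cest = np.linspace(-5.0, 5.0, 36)
    mt = np.array([7.5, 15.0, 30.0, 60.0, 100.0])
    offsets = np.concatenate([cest, mt, mt, [ref_ppm, ref_ppm]])
    flips = np.concatenate(
        [np.full(36, 180.0), np.full(5, 180.0), np.full(5, 540.0), [180.0, 540.0]]
    )
    return AcquisitionSchedule(offsets, flips)


def invivo_schedule(
    sat_flip_deg: float = 184.0, ref_ppm: float = 800.0
) -> AcquisitionSchedule:
    """41 CEST offsets asymmetrically sampled over +-4.5 ppm (denser near
    the +-3.5 ppm amide/NOE resonances), MT offsets at two powers, and a
    reference point per power."""
    coarse = np.linspace(-4.5, 4.5, 25)
    dense = np.concatenate([np.linspace(2.75, 4.25, 8), np.linspace(-4.25, -2.75, 8)])
    cest = np.sort(np.concatenate([coarse, dense]))
    assert cest.size == 41
    mt = np.array([7.5, 15.0, 30.0, 60.0, 100.0])
    offsets = np.concatenate([cest, mt, mt, [ref_ppm, ref_ppm]])
    flips = np.concatenate(
        [
            np.full(cest.size, sat_flip_deg),
            np.full(5, sat_flip_deg),
            np.full(5, 540.0),
            [sat_flip_deg, 540.0],
        ]
    )
    return AcquisitionSchedule(offsets, flips)


# -- phantom geometry ----------------------------------------------------


@dataclass
class PhantomLayout:
    """Tube grid: shape, tube centres/radii and per-tube concentrations."""

    shape: tuple[int, int] = (64, 64)
    tubes: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = []
        for t in self.tubes:
            bsa, agarose = t["conc"]
            if bsa < 0 or agarose < 0:
                raise ValueError("concentrations must be non-negative")
            for s in seen:
                d = np.hypot(t["center"][0] - s["center"][0], t["center"][1] - s["center"][1])
                if d < t["radius"] + s["radius"]:
                    raise ValueError("tubes overlap")
            seen.append(t)

    def tube_mask(self, i: int) -> np.ndarray:
        t = self.tubes[i]
        yy, xx = np.mgrid[: self.shape[0], : self.shape[1]]
        return (yy - t["center"][0]) ** 2 + (xx - t["center"][1]) ** 2 <= t["radius"] ** 2

    def label_map(self) -> np.ndarray:
        lab = np.zeros(self.shape, dtype=int)
        for i in range(len(self.tubes)):
            lab[self.tube_mask(i)] = i + 1
        return lab

    @property
    def concentrations(self) -> list[tuple[float, float]]:
        return [t["conc"] for t in self.tubes]


def _grid_layout(concs: list[tuple[float, float]], shape, radius) -> PhantomLayout:
    ny, nx = shape
    cols = 3
    rows = int(np.ceil(len(concs) / cols))
    tubes = []
    for i, conc in enumerate(concs):
        r, c = divmod(i, cols)
        cy = (r + 0.5) * ny / rows
        cx = (c + 0.5) * nx / cols
        tubes.append({"center": (cy, cx), "radius": radius, "conc": conc})
    return PhantomLayout(shape=shape, tubes=tubes)


def bsa_series_layout(shape=(64, 64), radius=7.0) -> PhantomLayout:
    """Variable-BSA series: 0, 1.8, 3.6, 7.2, 9% w/v BSA at 0.65% w/v
    agarose, plus a 6% BSA / 0.78% agarose comparison tube."""
    concs = [
        (0.0, 0.65), (1.8, 0.65), (3.6, 0.65),
        (7.2, 0.65), (9.0, 0.65), (6.0, 0.78),
    ]
    return _grid_layout(concs, shape, radius)


def agarose_series_layout(shape=(64, 64), radius=7.0) -> PhantomLayout:
    """Variable-agarose series: 0 to 1.3% w/v agarose at 6% w/v BSA."""
    concs = [(6.0, a) for a in (0.0, 0.26, 0.52, 0.78, 1.04, 1.3)]
    return _grid_layout(concs, shape, radius)


def generate_field_maps(
    shape: tuple[int, int],
    b0_amplitude_ppm: float,
    b1_amplitude: float,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Smooth low-order polynomial B0 (ppm) and relative B1 maps.

    B0 is bounded by +-b0_amplitude_ppm; B1 has mean ~1 and deviation
    bounded by +-b1_amplitude.
    """
    if b0_amplitude_ppm < 0 or b1_amplitude < 0:
        raise ValueError("field amplitudes must be non-negative")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    u = 2.0 * yy / max(shape[0] - 1, 1) - 1.0
    v = 2.0 * xx / max(shape[1] - 1, 1) - 1.0
    basis = [u, v, u * v, u**2, v**2]

    def smooth(amplitude):
        if amplitude == 0:
            return np.zeros(shape)
        f = sum(c * b for c, b in zip(rng.normal(size=len(basis)), basis))
        f -= f.mean()
        peak = np.max(np.abs(f))
        return f / peak * amplitude if peak > 0 else f

    return smooth(b0_amplitude_ppm), 1.0 + smooth(b1_amplitude)


def generate_phantom_image(
    layout: PhantomLayout,
    scheme: SaturationScheme,
    schedule: AcquisitionSchedule,
    noise_sd: float = 0.005,
    b0_amplitude_ppm: float = 0.05,
    b1_amplitude: float = 0.05,
    seed: int = 0,
    conc_map: ConcentrationMap | None = None,
):
    """Simulate a noisy 4D Z-spectrum stack for a tube phantom.

    Returns ``(data4d, truth, t1_map, b1_map)`` where ``data4d`` has shape
    ``layout.shape + (len(schedule),)`` (normalized signal + Gaussian
    noise), and ``truth`` maps parameter names to ground-truth images
    (including the B0 map).  Deterministic for a given seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    b0_map, b1_map = generate_field_maps(
        layout.shape, b0_amplitude_ppm, b1_amplitude, seed=seed
    )
    data = np.zeros(layout.shape + (len(schedule),))
    truth = {
        k: np.full(layout.shape, np.nan)
        for k in ("amide_m0r", "noe_m0r", "semisolid_m0r", "water_t1", "b0_ppm")
    }
    t1_map = np.full(layout.shape, np.nan)

    models = [
        SteadyStateModel(make_pool_system("bsa_agarose", conc, conc_map), scheme)
        for conc in layout.concentrations
    ]
    cache: dict[tuple, np.ndarray] = {}
    for i, model in enumerate(models):
        sys_ = model.system
        for idx in np.argwhere(layout.tube_mask(i)):
            idx = tuple(idx)
            key = (i, float(b0_map[idx]), float(b1_map[idx]))
            if key not in cache:
                cache[key] = model.zspectrum(
                    schedule, b0_shift_ppm=key[1], b1_scale=key[2]
                ).values
            data[idx] = cache[key]
            truth["amide_m0r"][idx] = sys_.get("amide").m0r
            truth["noe_m0r"][idx] = sys_.get("noe").m0r
            truth["semisolid_m0r"][idx] = sys_.get("semisolid").m0r
            truth["water_t1"][idx] = sys_.get("water").t1
            truth["b0_ppm"][idx] = b0_map[idx]
            t1_map[idx] = sys_.get("water").t1
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    return data, truth, t1_map, b1_map
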