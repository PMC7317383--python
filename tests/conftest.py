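import numpy as np
import pytest

from cestqmt import (
    AcquisitionSchedule,
    Pool,
    PoolSystem,
    SaturationScheme,
)


@pytest.fixture(scope="session")
def scheme180():
    """Reference pulsed scheme: fifty 20-ms Gaussian pulses, 50% duty,
    180 deg saturation flip, 7 deg excitation."""
    return SaturationScheme(sat_flip_deg=180.0, exc_flip_deg=7.0)


@pytest.fixture(scope="session")
def water_pool():
    return Pool("water", 0.0, 1.0, 0.07, 1.0)


@pytest.fixture(scope="session")
def brain3(water_pool):
    """Water + amide + super-Lorentzian semisolid three-pool system."""
    return PoolSystem(
        [
            water_pool,
            Pool("amide", 3.5, 1.0, 0.010, 0.005302, 30.0),
            Pool("semisolid", 0.0, 1.0, 10e-6, 0.20, 20.0,
                 klass="semisolid", lineshape="super_lorentzian"),
        ]
    )


@pytest.fixture(scope="session")
def small_schedule():
    offs = np.array([-3.5, -1.0, 1.0, 3.5, 15.0, 800.0])
    return AcquisitionSchedule(offs, np.full(offs.size, 180.0))


def random_system(rng: np.random.Generator) -> PoolSystem:
    """Random but physically sane pool system for property tests."""
    pools = [Pool("water", 0.0, rng.uniform(0.5, 3.0), rng.uniform(0.03, 1.0), 1.0)]
    for i in range(rng.integers(0, 3)):
        pools.append(
            Pool(
                f"solute{i}",
                rng.uniform(-4.0, 4.0),
                rng.uniform(0.5, 2.0),
                rng.uniform(0.002, 0.05),
                rng.uniform(0.0005, 0.02),
                rng.uniform(10.0, 1000.0),
            )
        )
    if rng.random() < 0.7:
        pools.append(
            Pool(
                "mt",
                rng.uniform(-2.5, 0.0),
                1.0,
                rng.uniform(5e-6, 3e-5),
                rng.uniform(0.01, 0.3),
                rng.uniform(5.0, 60.0),
                klass="semisolid",
                lineshape=rng.choice(["gaussian", "super_lorentzian", "lorentzian"]),
            )
        )
    return PoolSystem(pools)


def random_scheme(rng: np.random.Generator) -> SaturationScheme:
    duty = rng.uniform(0.3, 1.0)
    pulse_dur = rng.uniform(0.005, 0.03)
    n_pulses = int(rng.integers(5, 40))
    t_m = n_pulses * pulse_dur / duty
    return SaturationScheme(
        n_pulses=n_pulses,
        pulse_dur=pulse_dur,
        duty_cycle=duty,
        pulse_shape=rng.choice(["gaussian", "block"]),
        sat_flip_deg=rng.uniform(30.0, 540.0),
        exc_flip_deg=rng.uniform(0.0, 30.0),
        shot_interval=t_m + 0.01 + rng.uniform(0.05, 1.0),
        t_s=0.01,
    )
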