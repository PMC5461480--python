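import numpy as np
import pytest

from myovasim import ActinFilament, MotorParams, SimConfig, make_intersection


@pytest.fixture(scope="session")
def motor_params() -> MotorParams:
    return MotorParams()


@pytest.fixture()
def long_filament() -> ActinFilament:
    return ActinFilament(origin=[0.0, -5000.0, 0.0], direction=[0.0, 1.0, 0.0],
                         length=10000.0)


@pytest.fixture(scope="session")
def short_run_trajectory():
    """One seeded single-filament run reused across read-only tests."""
    from myovasim import simulate
    return simulate(SimConfig(seed=3, max_time=8.0))


@pytest.fixture(scope="session")
def intersection_run():
    """One seeded intersection transit (trajectory, record, geometry)."""
    from myovasim import run_intersection
    inter = make_intersection(100.0, 1)
    traj, rec = run_intersection(SimConfig(seed=11, geometry=inter,
                                           max_time=25.0))
    return traj, rec, inter
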