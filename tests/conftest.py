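import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gelprint import (
    ChannelGeometry,
    GridSpec,
    MaterialProperties,
    PowerLawModel,
    ProcessConditions,
    run_simulation,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def geometry():
    return ChannelGeometry()


@pytest.fixture(scope="session")
def material():
    return MaterialProperties(rheology=PowerLawModel(k=5.0, n=0.45, T_ref=25.0, b=0.12))


@pytest.fixture(scope="session")
def warm_conditions():
    """Reference operating point: 0.03 mm/s feed at 30 degC into 5 degC ambient."""
    return ProcessConditions(inlet_velocity=0.03, initial_material_temperature=30.0)


@pytest.fixture(scope="session")
def inlet_velocity_sweep(geometry, material):
    """Transient runs across the printer's inlet-velocity window (shared:
    these are the most expensive fixtures in the suite)."""
    results = {}
    for vj in (0.03, 0.05, 0.07, 0.09):
        cond = ProcessConditions(inlet_velocity=vj, initial_material_temperature=30.0)
        results[vj] = run_simulation(geometry, cond, material, duration=600.0)
    return results


@pytest.fixture(scope="session")
def grid_halving_runs(geometry, material, warm_conditions):
    """The same run on the default grid and with both dr and dz halved."""
    coarse = run_simulation(geometry, warm_conditions, material,
                            grid=GridSpec(nr=33, nz=80), duration=300.0)
    fine = run_simulation(geometry, warm_conditions, material,
                          grid=GridSpec(nr=65, nz=160), duration=300.0)
    return coarse, fine


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
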