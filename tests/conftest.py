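import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from corneamech import (
    CalibrationCornea,
    CorneaGeometry,
    ModelConstants,
    ShellCoefficients,
    SyntheticSpec,
    draw_true_states,
    simulate_readings,
    write_cohort_csv,
)


@pytest.fixture(scope="session")
def constants():
    return ModelConstants()


@pytest.fixture(scope="session")
def mean_geometry():
    """Reference-cohort mean geometry (R = 7.75 mm, t = 549.9 μm)."""
    return CorneaGeometry(7.75, 0.5499)


@pytest.fixture(scope="session")
def mean_coeffs(mean_geometry, constants):
    return ShellCoefficients.from_geometry(mean_geometry, constants)


@pytest.fixture(scope="session")
def calibration(constants):
    return CalibrationCornea.reference(constants)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture()
def synthetic_csv(tmp_path):
    """A small noisy synthetic cohort written in the canonical CSV schema."""
    spec = SyntheticSpec(n_subjects=20, seed=7)
    states = draw_true_states(spec)
    records = simulate_readings(states, spec)
    path = tmp_path / "cohort.csv"
    write_cohort_csv(records, path)
    return path
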