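import numpy as np
import pytest

from fibriltools.geometry import measure_all
from fibriltools.simulate import SimulationSpec, simulate_study


@pytest.fixture(scope="session")
def study_cohort():
    """One seeded 195-chain study at the default conditions (P = 0.74 um)."""
    spec = SimulationSpec(seed=20211105)
    traces, manifest = simulate_study(spec)
    return spec, traces, manifest


@pytest.fixture(scope="session")
def study_geometry(study_cohort):
    _, traces, _ = study_cohort
    geometry, exclusions = measure_all(traces)
    assert not exclusions
    return geometry


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
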