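import numpy as np
import pytest

import grassaudit as ga


@pytest.fixture(scope="session")
def scheme():
    return ga.default_scheme()


@pytest.fixture(scope="session")
def small_study():
    """A small but complete simulated study shared across tests."""
    spec = ga.StudySpec(
        n_sites=6,
        psus_per_site=11,
        sampling=ga.SamplingConfig(radius_km=1.0),
    )
    return ga.simulate_study(spec, seed=42)


@pytest.fixture(scope="session")
def design_study():
    """A study at the design's 5-km radius, large enough for composition checks."""
    return ga.simulate_study(ga.StudySpec(n_sites=30, psus_per_site=11), seed=2024)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
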