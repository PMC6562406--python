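import numpy as np
import pytest

from histoptm import library as lib
from histoptm import simulate as sim


@pytest.fixture(scope="session")
def default_library():
    return lib.PeptideLibrary.build()


@pytest.fixture(scope="session")
def noise_free_truth(default_library):
    """Tiny noise-free cohort with the default tumor effect."""
    cfg = sim.CohortConfig(
        groups={"normal": 1, "tumor": 1},
        noise_sd=0.0,
        sample_scale_sd=0.0,
        seed=11,
    )
    return sim.generate_cohort(cfg, default_library)


@pytest.fixture(scope="session")
def noisy_cohort(default_library):
    """Default study conditions: 8 vs 8, K14ac fold change 0.5, sd 0.2."""
    return sim.generate_cohort(sim.CohortConfig(seed=5), default_library)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
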