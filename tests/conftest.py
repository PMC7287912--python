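import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240515)


@pytest.fixture
def roi_set():
    from fcgraph import default_roi_set

    return default_roi_set()


def random_adjacency(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    """Erdos-Renyi-style random binary symmetric adjacency."""
    upper = rng.random((n, n)) < p
    adj = np.triu(upper, k=1).astype(np.int8)
    return adj | adj.T


@pytest.fixture
def small_cohort():
    """A 4-subject, 60-volume cohort: fast enough for pipeline tests."""
    from fcgraph import SyntheticCohortConfig, generate_cohort

    config = SyntheticCohortConfig(n_subjects=4, n_volumes=60, seed=7)
    return generate_cohort(config)
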