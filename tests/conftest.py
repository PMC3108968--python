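import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from minkmds.datasets import load_germany_example
from minkmds.metrics import Configuration, pairwise_distances
from minkmds.survey import ThreeWayDissimilarities, profile_dissimilarities

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def germany():
    return load_germany_example()


@pytest.fixture(scope="session")
def germany_dissim(germany):
    return profile_dissimilarities(germany, p_in=2.0)


@pytest.fixture(scope="session")
def small_cityblock_data():
    """Noise-free three-way data from a known 6-party planar configuration."""
    rng = np.random.default_rng(12)
    coords = rng.uniform(-1.0, 1.0, (6, 2))
    cfg = Configuration(labels=[f"P{i}" for i in range(6)], coords=coords, metric_p=1.0)
    d = pairwise_distances(cfg)
    return coords, ThreeWayDissimilarities.from_matrices(
        cfg.labels, [d, d], profile_metric_p=1.0
    )
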