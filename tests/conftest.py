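import numpy as np
import pytest

from stuntmap.synthetic_data import SimulationConfig, simulate_survey


def small_config(seed=7, **overrides) -> SimulationConfig:
    """Desk-scale survey: 2x2 degree domain, 120 clusters, ~12 children each."""
    kwargs = dict(
        seed=seed,
        n_admin1=6,
        n_admin2_per_admin1=4,
        n_clusters=120,
        children_per_cluster_mean=12,
        domain_bbox=(10.0, 6.0, 12.0, 8.0),
        raster_cellsize=0.02,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def survey():
    """One shared synthetic survey for read-only tests."""
    return simulate_survey(small_config())


@pytest.fixture(scope="session")
def children_with_coords(survey):
    return survey.children.merge(
        survey.clusters[["cluster_id", "lon", "lat", "admin1_id"]], on="cluster_id"
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
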