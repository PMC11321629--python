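import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import diseasemap as dm

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_dataset():
    """Default synthetic study conditions (60 diseases, 3 planted clusters)."""
    tables, truth = dm.generate(dm.SyntheticConfig(seed=1))
    return tables, truth


@pytest.fixture(scope="session")
def intersected(default_dataset):
    """Incidence matrices restricted to the cross-dimension disease set."""
    tables, truth = default_dataset
    incs = {d: dm.to_incidence(t) for d, t in tables.items()}
    dims = list(incs)
    return dict(zip(dims, dm.intersect_diseases([incs[d] for d in dims]))), truth


@pytest.fixture(scope="session")
def consensus_chain(intersected):
    """Full fusion chain on the default dataset: metric and dimension consensus."""
    incs, truth = intersected
    dim_cons = {
        d: dm.metric_consensus(dm.all_metric_matrices(inc))[0] for d, inc in incs.items()
    }
    consensus, fam = dm.dimension_consensus(dim_cons)
    return dim_cons, consensus, fam, truth


def random_distance_matrix(rng: np.random.Generator, n: int) -> dm.DistanceMatrix:
    """Random valid DistanceMatrix (helper shared across test modules)."""
    v = rng.random((n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    return dm.DistanceMatrix([f"D{i:03d}" for i in range(n)], v)
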