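import numpy as np
import pytest

from vaxmono import ClusterDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_cluster_dataset(rng, m=12, p_cov=2, integer=True):
    """A small valid ClusterDataset with monotone counts."""
    n = rng.integers(2, 30, m).astype(float)
    y1 = np.floor(n * rng.uniform(0, 1, m))
    y2 = np.floor(y1 * rng.uniform(0, 1, m))
    y3 = np.floor(y2 * rng.uniform(0, 1, m))
    if not integer:
        u = rng.uniform(0.2, 0.9, (m, 3))
        y1 = n * u[:, 0]
        y2 = y1 * u[:, 1]
        y3 = y2 * u[:, 2]
    return ClusterDataset(
        cluster_id=np.array([f"c{i}" for i in range(m)], dtype=object),
        coords=rng.uniform(0, 8, (m, 2)),
        n=n,
        y=np.column_stack([y1, y2, y3]),
        covariates=rng.standard_normal((m, p_cov)),
        covariate_names=[f"x{j}" for j in range(p_cov)],
    )


@pytest.fixture
def small_dataset(rng):
    return random_cluster_dataset(rng)
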