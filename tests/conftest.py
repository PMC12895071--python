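import numpy as np
import pytest

from sper.datatypes import CompositionMatrix, ExpressionMatrix, SpotGeometry


def grid_geometry(side: int, spacing: float = 100.0) -> SpotGeometry:
    rr, cc = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    coords = np.column_stack([cc.reshape(-1), rr.reshape(-1)]).astype(float) * spacing
    ids = [f"s{r}_{c}" for r in range(side) for c in range(side)]
    return SpotGeometry(ids, coords, spacing=spacing)


def random_instance(rng, n_max=100, m_max=10, k_max=4):
    """A random small scored instance: normalized E, simplex C, scattered spots."""
    n = int(rng.integers(10, n_max + 1))
    m = int(rng.integers(2, m_max + 1))
    k = int(rng.integers(2, k_max + 1))
    coords = rng.uniform(0, 1000, size=(n, 2))
    counts = rng.poisson(rng.uniform(0.5, 8.0, size=m), size=(n, m)).astype(float)
    counts[0] += 1  # avoid all-zero genes in oracle comparisons
    means = counts.mean(axis=0)
    E_norm = counts / np.where(means > 0, means, 1.0)
    raw = rng.dirichlet(np.ones(k), size=n).T
    spot_ids = [f"s{i}" for i in range(n)]
    gene_ids = [f"g{i}" for i in range(m)]
    expr = ExpressionMatrix(spot_ids, gene_ids, E_norm, normalized=True)
    comp = CompositionMatrix([f"t{i}" for i in range(k)], spot_ids, raw)
    geom = SpotGeometry(spot_ids, coords, spacing=100.0)
    return expr, comp, geom


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_grid():
    return grid_geometry(5)


@pytest.fixture
def toy_instance(rng):
    return random_instance(rng, n_max=40, m_max=6, k_max=3)
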