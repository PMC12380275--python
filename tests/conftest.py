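import numpy as np
import pytest

from chrombench import (
    GenomicRegion,
    ModelEnsemble,
    PolymerModel,
    SpringNetworkSpec,
    SquareMatrix,
    make_benchmark_scene,
    sample_ensemble,
)


@pytest.fixture
def region():
    return GenomicRegion("chrT", 0, 10000)


@pytest.fixture
def line_model(region):
    """10 collinear, uniformly spaced beads along x."""
    coords = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
    return PolymerModel(coords, region, 1000, label="line")


@pytest.fixture
def random_walk_model(region):
    rng = np.random.default_rng(42)
    coords = np.cumsum(rng.standard_normal((50, 3)), axis=0)
    return PolymerModel(coords, region, 200, label="walk")


@pytest.fixture
def small_ensemble(region):
    """3 distinct random-walk conformations sharing shape and region."""
    rng = np.random.default_rng(7)
    models = [
        PolymerModel(np.cumsum(rng.standard_normal((20, 3)), axis=0),
                     region, 500, label="ens")
        for _ in range(3)
    ]
    return ModelEnsemble(models, label="ens")


def square(values, kind="distance", region=None, bp=1000, **kw):
    """Build a SquareMatrix from a symmetric array with defaults filled in."""
    values = np.asarray(values, dtype=float)
    if region is None:
        region = GenomicRegion("chrT", 0, int(values.shape[0] * bp))
    return SquareMatrix(values, kind=kind, region=region, bp_per_bin=bp, **kw)


def from_upper(upper, n, **kw):
    """Symmetric matrix from strictly-upper-triangle entries (row-major)."""
    m = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    m[iu, ju] = upper
    m = m + m.T
    return square(m, **kw)


@pytest.fixture(scope="session")
def scene():
    """Small benchmark scene shared across tests (60 beads keeps it fast)."""
    return make_benchmark_scene(seed=11, n_beads=60, n_structures=80)


@pytest.fixture(scope="session")
def chain_ensemble_2000():
    """Large chain-only ensemble for the Gaussian closed-form checks."""
    spec = SpringNetworkSpec(n_beads=50, backbone_strength=1.0, seed=123)
    return spec, sample_ensemble(spec, 2000)
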