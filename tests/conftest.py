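import numpy as np
import pytest

from gparcel.profile_io import ProfileMatrix
from gparcel.similarity import SimilarityMatrix
from gparcel.synthetic import make_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_graded_cohort():
    """A small graded cohort shared across tests (read-only)."""
    return make_cohort(n_seeds=60, n_participants=4, K=4, regime="graded",
                       noise=0.05, rng_seed=42, grid=(16, 16, 16))


@pytest.fixture
def random_similarity(rng):
    """A dense random symmetric non-negative similarity matrix, unit diagonal."""
    def _make(n, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        A = r.random((n, n))
        S = (A + A.T) / 2
        np.fill_diagonal(S, 1.0)
        return SimilarityMatrix(values=S, seed_ids=[f"s{i}" for i in range(n)])
    return _make


def make_pm(values, grid_shape=None):
    """Wrap a raw array as a ProfileMatrix with an identity column map."""
    values = np.asarray(values, dtype=float)
    m = values.shape[1]
    if grid_shape is None:
        grid_shape = (m, 1, 1)
    return ProfileMatrix(values=values,
                         seed_ids=[f"s{i}" for i in range(values.shape[0])],
                         column_map=np.arange(m), grid_shape=grid_shape)
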