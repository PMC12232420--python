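import numpy as np
import pytest

from scanchor import OmicsView, SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_pair():
    """Small, well-separated paired dataset for fast end-to-end tests."""
    spec = SyntheticSpec(
        n_cells=120,
        n_clusters=3,
        d_rna=60,
        d_atac=90,
        rna_mean_separation=2.5,
        atac_open_prob_in=0.5,
        atac_open_prob_out=0.02,
        dropout_rate=0.2,
        seed=7,
    )
    return generate(spec)


@pytest.fixture
def tiny_view():
    mat = np.array([[1.0, 2.0, 0.0, 3.0], [0.0, 1.0, 1.0, 1.0], [2.0, 0.0, 1.0, 4.0]])
    return OmicsView(mat, "rna", ["g1", "g2", "g3"], ["c1", "c2", "c3", "c4"])


def random_orthonormal(rng, rows, cols):
    """Random matrix with orthonormal columns (QR of a Gaussian)."""
    Q, _ = np.linalg.qr(rng.normal(size=(rows, cols)))
    return Q[:, :cols]


def random_column_stochastic(rng, m, n):
    return rng.dirichlet(np.ones(m), size=n).T
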