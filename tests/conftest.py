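import numpy as np
import pytest

from liquidassoc import ExpressionMatrix, transform_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def noise_matrix(rng):
    """Small all-noise transformed matrix (10 genes x 40 samples)."""
    values = rng.standard_normal((10, 40))
    mat = ExpressionMatrix(
        gene_ids=[f"g{i}" for i in range(10)],
        sample_ids=[f"s{j}" for j in range(40)],
        values=values,
    )
    return transform_matrix(mat)


def planted_profiles(theta: float, m: int, rng) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Raw planted triplet with corr(x, y | z) = tanh(theta z)."""
    z = rng.standard_normal(m)
    w = rng.standard_normal(m)
    e = rng.standard_normal(m)
    c = np.tanh(theta * z)
    return w, c * w + np.sqrt(1.0 - c**2) * e, z
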