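import numpy as np
import pytest

from mixge import DesignBundle


@pytest.fixture
def toy_bundle() -> DesignBundle:
    """N=6, p=2 bundle with hand-chosen integer entries (default W = 1/p)."""
    Y = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0])
    X = np.ones((6, 1))
    E = np.array([1.0, -1.0, 2.0, 0.0, 1.0, -2.0])
    G = np.array([
        [0, 1],
        [1, 0],
        [2, 1],
        [0, 0],
        [1, 2],
        [2, 0],
    ], dtype=float)
    return DesignBundle(Y=Y, X=X, E=E, G=G)


@pytest.fixture
def gaussian_bundle() -> DesignBundle:
    """Moderate continuous-phenotype bundle for distributional checks."""
    rng = np.random.default_rng(12345)
    n, p = 300, 5
    maf = rng.uniform(0.1, 0.5, p)
    u = rng.random((n, p))
    G = ((u >= (1 - maf) ** 2).astype(float)
         + (u >= (1 - maf) ** 2 + 2 * maf * (1 - maf)).astype(float))
    E = rng.standard_normal(n)
    X = np.column_stack([np.ones(n), rng.standard_normal(n)])
    Y = 0.5 * E + G @ rng.normal(0, 0.3, p) + rng.standard_normal(n)
    return DesignBundle(Y=Y, X=X, E=E, G=G)
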