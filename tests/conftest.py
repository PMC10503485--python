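import numpy as np
import pytest

from relief_harmonize import CovariateDesign, ScannerPartition


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def two_scanner_partition():
    """Two scanners of sizes 6 and 8."""
    return ScannerPartition(np.repeat(["a", "b"], [6, 8]))


def make_dataset(rng, V=12, sizes=(6, 8), q=2, scanner_shift=0.0, scale=(1.0, 1.0)):
    """Small synthetic dataset with known covariate effects and scanner structure."""
    n = sum(sizes)
    partition = ScannerPartition(np.repeat([f"s{i}" for i in range(len(sizes))], sizes))
    X = rng.standard_normal((n, q))
    beta = rng.standard_normal((V, q))
    intercepts = rng.standard_normal(V)
    noise = rng.standard_normal((V, n))
    for i, idx in enumerate([partition.indices(i) for i in range(partition.n_scanners)]):
        noise[:, idx] *= scale[i]
        noise[:, idx] += scanner_shift * i
    Y = intercepts[:, None] + beta @ X.T + noise
    return Y, CovariateDesign(X), partition, {"beta": beta, "intercepts": intercepts}


@pytest.fixture
def small_dataset(rng):
    return make_dataset(rng)
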