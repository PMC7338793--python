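import numpy as np
import pytest

from eegsift import (
    DecompositionConfig,
    SyntheticConfig,
    generate_synthetic_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_bundle():
    """20+20 records, 512 samples: enough for pipeline-level checks."""
    cfg = SyntheticConfig(n_per_class=20, n_samples=512, seed=7)
    return generate_synthetic_dataset(cfg)


@pytest.fixture(scope="session")
def fast_decomp_config():
    """Small ensemble so ensemble decompositions stay quick in unit tests."""
    return DecompositionConfig(ensemble_pairs=4)


@pytest.fixture
def toy_xy():
    """Linearly separable 2-D toy: class by sign of the first feature."""
    rng = np.random.default_rng(3)
    n = 40
    x = rng.normal(size=(n, 2))
    x[: n // 2, 0] += 3.0
    x[n // 2 :, 0] -= 3.0
    y = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
    return x, y
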