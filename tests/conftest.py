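import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def hw_genotypes():
    """Hardy-Weinberg genotype draw at given shape; deterministic per call site."""

    def _make(n, m, seed=7, maf_low=0.1, maf_high=0.5):
        g = np.random.default_rng(seed)
        return g.binomial(2, g.uniform(maf_low, maf_high, m), size=(n, m)).astype(float)

    return _make


@pytest.fixture
def planted_coefficients():
    """Sparse M x K coefficient matrix with ``n`` unit-magnitude effects."""

    def _make(m, k, n, seed=13, magnitude=1.0):
        g = np.random.default_rng(seed)
        b = np.zeros((m, k))
        idx = g.choice(m * k, size=n, replace=False)
        b.ravel()[idx] = magnitude * g.choice([-1.0, 1.0], size=n)
        return b

    return _make
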