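"""The bundled Polya-Gamma sampler and its closed-form moments.

PG auxiliaries are what make the Binomial and Negative Binomial Gibbs
samplers tractable: conditioned on omega ~ PG(b, c), a logistic likelihood
becomes Gaussian in its linear predictor.
"""

import numpy as np

from eqtlmap import pg_mean, pg_var, sample_pg

rng = np.random.default_rng(0)
for b, c in [(1.0, 0.0), (1.0, 2.0), (3.5, 1.0), (25.0, 0.5)]:
    draws = sample_pg(np.full(50000, b), np.full(50000, c), rng)
    print(
        f"PG({b:4}, {c:3}): empirical mean {draws.mean():.4f}  "
        f"exact {float(pg_mean(b, c)):.4f}   empirical var {draws.var():.5f}  "
        f"exact {float(pg_var(b, c)):.5f}"
    )
# E[PG(b,c)] = (b/2c) tanh(c/2); the sampler switches between an exact
# Devroye method, a truncated-series construction and a CLT approximation.
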