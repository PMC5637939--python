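"""Monte Carlo cross-validation: predictive agreement without knowing the truth.

Random 3:1 train/validation splits; each repeat fits on the training samples
and scores Lin's concordance correlation coefficient (CCC) between predicted
and observed expression on the held-out samples.  CCC near 1 means the model
predicts held-out expression almost perfectly on its comparison scale.
"""

from eqtlmap import McmcConfig, SimulationConfig, monte_carlo_cv, simulate_dataset

x, z, _ = simulate_dataset(
    SimulationConfig(n_samples=200, n_markers=10, n_transcripts=40, n_assoc=5, seed=8)
)
res = monte_carlo_cv(
    x, z, "normal", transform="arcsin", repeats=5, seed=0,
    cfg=McmcConfig(n_iter=600, burnin=300, seed=0),
)
for i, (c, n) in enumerate(zip(res.ccc_per_repeat, res.n_called_per_repeat)):
    print(f"repeat {i}: CCC = {c:.4f}   associations called = {n}")
print(f"mean CCC = {res.mean_ccc:.4f}")
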