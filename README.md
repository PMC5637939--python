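# eqtlmap

Sparse Bayesian mapping of multiple expression quantitative trait loci
(eQTLs) from paired genotype and RNA-seq data.

An eQTL is a genetic variant whose genotype is associated with the expression
of one or more genes. Given an N×M matrix **X** of minor-allele dosages
(entries 0/1/2 for N samples at M bi-allelic markers) and an N×K matrix
**Z** of RNA-seq read counts for K transcripts, `eqtlmap` estimates the M×K
coefficient matrix **B** whose entry β<sub>jk</sub> is the effect of marker
*j* on transcript *k* — for *all* markers and transcripts simultaneously,
rather than one pair at a time. It is aimed at analyses where a set of
variants and transcripts has been pre-selected (clinically or by annotation)
and synergistic multi-variant effects matter.

## The model

Four regression likelihoods share one sparsity-inducing prior:

* **normal** — y<sub>ik</sub> ~ N(μ<sub>k</sub> + **x**<sub>i</sub>·**β**<sub>k</sub>, τ<sub>k</sub><sup>−1</sup>)
  on transformed counts **Y** (see below);
* **pois** — z<sub>ik</sub> ~ Poisson(exp(y<sub>ik</sub> + o<sub>i</sub>))
  with latent y<sub>ik</sub> ~ N(μ<sub>k</sub> + **x**<sub>i</sub>·**β**<sub>k</sub>, σ<sub>k</sub>²):
  a Poisson-LogNormal mixture (over-dispersed Poisson);
* **bin** — z<sub>ik</sub> ~ Binomial(n<sub>i</sub>, logit<sup>−1</sup>(y<sub>ik</sub>))
  with the same latent Gaussian layer (over-dispersed Binomial);
* **nbin** — z<sub>ik</sub> ~ NB(r<sub>k</sub>, logit<sup>−1</sup>(ψ<sub>ik</sub>)),
  ψ<sub>ik</sub> = μ<sub>k</sub> + o<sub>i</sub> + **x**<sub>i</sub>·**β**<sub>k</sub>.

Every coefficient carries the three-level shrinkage prior

β<sub>jk</sub> ~ N(0, τ<sub>k</sub><sup>−1</sup> ζ<sub>jk</sub><sup>−1</sup> η<sub>j</sub><sup>−1</sup>),
  τ, ζ, η ~ Jeffreys (∝ 1/θ),

so that most coefficients collapse onto zero without any tuning parameter;
small η<sub>j</sub> flags a *hotspot* marker (influencing many transcripts),
small τ<sub>k</sub> a *polygenic* transcript. Estimation is by Gibbs
sampling: in all four models the conditional posterior of **β**<sub>k</sub>
is multivariate Normal — exactly for the Normal model, and after latent
Gaussian pseudo-data (pois, bin) or Polya-Gamma auxiliaries
ω<sub>ik</sub> ~ PG(z<sub>ik</sub>+r<sub>k</sub>, ψ<sub>ik</sub>) (nbin),
which is what makes Negative Binomial multivariate regression tractable in
this framework. A bundled Polya-Gamma sampler (Devroye exact /
truncated-series / moment-matched Normal, chosen per element) provides the
auxiliaries.

For the Normal model the package implements the transformation suite:
log(z+1), per-gene Box-Cox on z+1, Blom rank scores, and Laplace-smoothed
multinomial proportions p<sub>ik</sub> = (z<sub>ik</sub>+c)/(Σ<sub>k</sub>z<sub>ik</sub>+cK)
followed by arcsin(√p) or logit(p). Externally transformed matrices (e.g.
voom or vst output from R) are accepted via `--transform none`.

Also included: a template-style simulator producing (X, Z, B_true) triplets
with Hardy-Weinberg genotypes and NB counts, the benchmarking metrics (MCC,
RMSE among true positives, Lin's CCC), a Monte Carlo cross-validation
harness, and Geweke joint-distribution tests for all four samplers.

## Worked example

```python
from eqtlmap import (McmcConfig, SimulationConfig, benchmark,
                     fit_nbin, simulate_dataset)

cfg = SimulationConfig(n_samples=300, n_markers=10, n_transcripts=20,
                       n_assoc=5, effect_rate=1.0, seed=42)
genotypes, counts, truth = simulate_dataset(cfg)
fit = fit_nbin(genotypes, counts, McmcConfig(n_iter=1500, burnin=750, seed=1))
result = benchmark(fit, truth)
```

Running this (`python examples/01_simulate_and_map.py`) prints

```
simulated 300 samples, 10 markers, 20 transcripts, 5 true effects
called associations : 5
true positives      : 5 of 5
false positives     : 0
MCC                 : 1.000
RMSE (true pos.)    : 0.020
```

i.e. of the 200 candidate marker-transcript pairs the sampler calls exactly
the 5 planted ones (Matthews correlation coefficient 1.0), and the planted
effect sizes are recovered to about 2% after max-abs normalization. The
other scripts in `examples/` demonstrate the transforms, a four-model
comparison, cross-validation and the Polya-Gamma sampler, each printing and
explaining its numbers.

The same analysis from the shell:

```sh
eqtlmap simulate --n 300 --m 10 --k 20 --n-assoc 5 --seed 42 --out sim/
eqtlmap run --model nbin --genotypes sim/genotypes.tsv \
    --expression sim/counts.tsv --out fit/ --iters 1500 --burnin 750 --seed 1 \
    --min-maf 0.05 --min-mean 10
eqtlmap evaluate --truth sim/truth.json --fit fit/ --out metrics.json
```

`eqtlmap run` also reads genotypes from a bi-allelic-SNV VCF
(`--geno-format vcf`), folds ALT dosages to minor-allele dosages, and applies
the standard cohort filters (MAF > 5%, mean count ≥ 10 reads).

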