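# Methods

## Model and prior

All four likelihoods regress expression on additive-coded genotypes
(0/1/2 minor-allele dosages). Genotype columns are mean-centered before
regression and each transcript carries a free intercept μ_k, because the
shrinkage prior is centered at zero: without centering, the prior would
shrink part of the intercept instead of the genetic effect.

The prior on each coefficient is β_jk ~ N(0, (τ_k ζ_jk η_j)^-1) with
independent Jeffreys priors p(θ) ∝ 1/θ on all three precisions. Jeffreys is
improper, parameter-free and strongly sparsity-inducing: the full
conditionals are Gamma,

    τ_k   ~ Gamma(M/2, ½ Σ_j ζ_jk η_j β_jk²)
    η_j   ~ Gamma(K/2, ½ Σ_k τ_k ζ_jk β_jk²)
    ζ_jk  ~ Gamma(1/2, ½ τ_k η_j β_jk²)

and a coefficient the data does not support is driven toward zero with
precision growing along the chain (clipped at 1e12; all precision draws are
clipped to [1e-12, 1e12] because the conditionals are heavy-tailed and the
bounds prevent overflow without materially affecting inference). In the
Normal model τ_k doubles as the residual precision, so its conditional gains
the residual term: τ_k ~ Gamma((N+M)/2, ½(RSS_k + Σ_j ζ_jk η_j β_jk²)).
This identification (rather than a separate noise precision) keeps the
parameter list to exactly τ, ζ, η and makes the β_k conditional
A_k = τ_k (XᵀX + diag(ζ_k ∘ η)).

Conditional β_k updates are multivariate Normal in all models and are drawn
via Cholesky factorizations of the K per-transcript precision matrices,
batched across transcripts (never an explicit inverse; a 1e-8 ridge retry
guards rank-deficient corner cases). Transcripts are conditionally
independent given X, so the sweep is vectorized over k.

## Count-model augmentations

* **pois** (Poisson-LogNormal): the latent log-rate y_ik has no conjugate
  update and moves by per-entry random-walk Metropolis with a per-entry
  step adapted during burn-in only (Robbins-Monro on the log step, target
  acceptance 0.40, rate 0.1). Acceptance statistics are reported over
  post-burn-in sweeps and typically sit in (0.2, 0.6).
* **bin**: Polya-Gamma auxiliaries ω_ik ~ PG(n_i, y_ik) make the latent y
  conditionally Gaussian; every update is then an exact Gibbs draw.
* **nbin**: ω_ik ~ PG(z_ik + r_k, ψ_ik) yields Gaussian pseudo-data
  (z_ik − r_k)/(2ω_ik) with precision ω_ik; the dispersion r_k moves by
  adaptive random-walk Metropolis on log r_k against the marginal NB
  likelihood (the ω are integrated out, which is valid because they are
  redrawn before next use). log r proposals are clipped to ±10.
* Over-dispersion in pois/bin lives in the latent variance σ_k², given an
  InverseGamma(1, 1) prior (conjugate); linear predictors are clipped at
  ±30 before exponentiation to prevent overflow; the clip is far outside
  the region any fitted model visits.

Offsets: pois and nbin use log median-of-ratios size factors; bin uses
median-of-ratios depth estimates (scaled to the mean library size, floored
at each row's maximum count) as denominators. Total-count offsets were
rejected deliberately: when K is small a few strongly-affected transcripts
shift the library size itself, so total-count factors absorb genetic signal
and leak it into every other transcript as spurious association. The
median-of-ratios estimator is robust to a minority of affected transcripts;
on self-simulated data with K=20 it removes the leakage entirely (null
signal-to-noise ratios drop from ~3-4 to <2, detection MCC rises from
0.5-0.8 to 1.0).

## Transformations

`laplace_smooth` maps counts to p_ik = (z_ik + c)/(Σ_k z_ik + cK), c = 1 by
default; every entry then lies strictly between the empirical proportion and
the uniform 1/K, rows sum to exactly 1, and `arcsin` (arcsin √p) or `logit`
carries them to the real line. Counts can be divided by total-count size
factors first (`normalize`); the default is no normalization. Box-Cox λ is
estimated per transcript by bounded profile-likelihood maximization on z+1
over λ ∈ [−2, 2] (per-gene rather than global, because gene-wise
mean-variance heterogeneity makes a single λ a poor compromise); λ = 0
reproduces log(z+1) exactly. Blom scores use the classical constants
Φ⁻¹((r − 3/8)/(N + 1/4)) with average ranks for ties, so a constant column
maps to zeros and the output depends on the data only through ranks.
Natural logarithms throughout. voom/vst are not reimplemented; their output
can be supplied as a pre-transformed matrix to the Normal model.

## Polya-Gamma sampler

Per-element route selection: Devroye's exact alternating-series rejection
sampler for b = 1 and small integer b (≤ 4); a truncated-series construction
(100 Gamma(b,1)-weighted terms, deterministic tail-mean correction, mean
error O(10⁻⁴·b), missing tail variance O(10⁻⁵) relative) for other b < 13;
a moment-matched Normal approximation for b ≥ 13, where PG(b, c) is a sum of
b ≥ 13 iid variables and the CLT error is negligible (draws floored at
1e-12). The truncated series with 200 terms doubles as the independent
oracle in the tests. In the NB sampler the shape is z_ik + r_k, so the fast
Normal route dominates at realistic counts.

## Association calling

An entry is called when |posterior median of β_jk| > t · (posterior SD of
β_jk), default t = 3 (exposed as `--call-threshold`). Under the shrinkage
prior, null coefficients collapse onto zero with sign-symmetric draws, so
the rule is extremely conservative for them; a supported coefficient has a
median tens of SDs from zero. A global MAD-of-medians scale was considered
and rejected: under Jeffreys shrinkage the null medians span many orders of
magnitude around ~1e-13, so any global scale estimate collapses and
numerically-zero entries get "called". The threshold 3 is calibrated so
that a whole-matrix null analysis (200 candidate pairs) produces any call in
fewer than 5% of replicate datasets while leaving detection of unit-scale
effects unaffected (MCC 1.0 on self-simulated data for all four models).

## Simulator

`simulate_dataset` emulates population-cohort structure without external
template files: per-marker MAF ~ Uniform(0.05, 0.5) with Hardy-Weinberg
dosages Binomial(2, maf); per-gene baseline means LogNormal(log 100, 1)
(library-scale counts, a realistic dynamic range) and NB dispersions
Gamma(2, 0.2) (mean 10, i.e. squared biological CV ~0.1-1); effect
magnitudes Exponential(rate 2, mean 0.5 on the log scale) truncated at
log 4, signs ±½. The truncation keeps per-allele fold changes within the
range reported for strong eQTLs; it also matters structurally at desk
scale: with only K=100 transcripts, an untruncated tail effect (e.g.
|β| = 2.8 → 16-fold per allele) makes one gene dominate the library, so
every *proportion* shifts with that marker and proportion-based models
acquire compositional false positives that have nothing to do with mapping
ability (at the realistic K ~ 1000 this artifact vanishes). Association
patterns: optional hotspots (a marker hitting ⌈0.1K⌉ random transcripts) and
polygenic transcripts (⌈0.1M⌉ random markers); remaining associations land
uniformly. Two noise mechanisms: expression outliers (an entry is multiplied
by 0.1 or 10 with the configured probability — aggressive contamination of
the kind bounded transforms tolerate and count likelihoods do not) and
genotype resampling from the marker's Hardy-Weinberg law.

What the simulator does *not* emulate: linkage disequilibrium between
markers, GC/length biases, batch effects, isoform structure, or empirically
estimated per-gene mean/dispersion profiles from real cohorts (users can
approximate the latter by setting the log-normal/Gamma hyperparameters).
Passing benchmarks on this generator therefore demonstrates correctness and
relative model behavior under controlled conditions, not performance on any
particular real cohort. `simulate_from_model` additionally draws expression
from each fitted model's own generative process for correctly-specified
recovery checks.

## Validation design

* **Exactness**: the Normal β conditional is checked against an independent
  dense ridge solve; the PG sampler against closed-form moments and the
  200-term series oracle; MCC/CCC against scikit-learn and the textbook
  formula.
* **Kernel correctness**: a Geweke-style successive-conditional test per
  sampler compares forward simulation (parameters from the prior, data from
  the likelihood) with the chain alternating the package's own sweep kernels
  and data redraws, on a 3-marker, 2-transcript toy with 10 samples and
  5000 sweeps (batch-means SEs; threshold |z| < 4). The harness uses proper
  priors — Gamma(10, 10) on precisions, N(0, ¼) intercepts,
  InverseGamma(5, 5) latent variances, LogNormal(log 8, 0.2) dispersions —
  through the *same* update code (the Gamma hyperprior parameters enter the
  conditionals additively and are zero during fitting, which recovers
  Jeffreys). Heavier-tailed harness priors were rejected after showing a
  mixing pathology: rare prior draws with |β| ~ 10 generate counts so
  informative that the successive chain is effectively absorbed.
* **Operating characteristics**: self-simulated recovery (N=400, M=10,
  K=20, five unit effects) must reach MCC ≥ 0.8 per model; 20 null
  replicates per model must produce calls in at most one run.
* **Benchmark orderings**: the scaled-down benchmark (M=20, K=100, 10
  effects, three replicates per sample size at expression-outlier noise
  0/1%/2%) checks that every model's mean MCC is non-decreasing from N=100
  to N=400 and that the over-dispersed Poisson is within 0.05 of (in
  practice well above) the Negative Binomial. The arcsin-vs-binomial
  comparison at N=100 is a statistical tie in this implementation
  (3-seed means 0.59 vs 0.60): this package's Binomial model benefits from
  the robust depth denominators and the latent-Gaussian over-dispersion
  layer, so it does not display the weakness that motivated that ordering.

Problem sizes and chain lengths in the test-suite (600-1200 iterations,
N ≤ 400, K ≤ 100) are deliberate desk-scale choices: they keep the full
validation cycle at minutes while leaving every conclusion
Monte-Carlo-stable. Library defaults for real analyses are 4000 iterations
with 2000 burn-in, single chain, no thinning, all randomness from one root
seed.

## Known limitations

* Single-chain inference; convergence diagnostics beyond the Geweke harness
  (R-hat across chains, ESS reporting) are not built in.
* The Metropolis latent update of `pois` adapts per entry during burn-in
  only; very sparse transcripts (all-zero columns) are fit but carry little
  information and are absorbed by the intercept.
* Posterior draws are held in memory ((iters − burnin) × M × K doubles);
  at the default chain length and M·K ≳ 10⁵ this reaches gigabytes — split
  markers into groups of a few hundred, which is also statistically
  advisable with this prior.
* Missing genotypes are imputed to the rounded per-marker mean dosage (the
  models have no missing-data mechanism); dosage uncertainty and phasing are
  out of scope.
* VCF input handles bi-allelic SNVs via GT fields; multi-allelic records
  are skipped with a warning.
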