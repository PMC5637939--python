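"""The four eQTL regression samplers: normal, pois, bin and nbin.

All four share the three-level shrinkage prior and Gibbs machinery of
:mod:`eqtlmap.sparse_prior`; they differ in how the observed expression enters:

* ``normal`` — y_ik ~ N(mu_k + x_i . beta_k, tau_k^-1) on transformed data;
  the transcript precision tau_k doubles as the residual precision.
* ``pois`` — z_ik ~ Poisson(exp(y_ik + o_i)) with a latent Gaussian rate
  y_ik ~ N(mu_k + x_i . beta_k, sigma_k^2): a Poisson-LogNormal mixture whose
  latent variance sigma_k^2 carries the over-dispersion.  The latent y has no
  conjugate update and moves by adaptive random-walk Metropolis.
* ``bin`` — z_ik ~ Binomial(n_i, sigmoid(y_ik)) with the same latent Gaussian
  y; Polya-Gamma auxiliaries omega_ik ~ PG(n_i, y_ik) make y conditionally
  Gaussian, so every update is a Gibbs draw.
* ``nbin`` — z_ik ~ NB(r_k, sigmoid(psi_ik)) with log-odds
  psi_ik = mu_k + o_i + x_i . beta_k; auxiliaries omega_ik ~ PG(z_ik + r_k,
  psi_ik) yield the Gaussian pseudo-data (z - r)/(2 omega), and the dispersion
  r_k moves by random-walk Metropolis on log r_k.

Offsets o_i are log total-count size factors (pois, nbin); the Binomial model
uses library sizes n_i as denominators instead.  Genotype columns are
mean-centered before regression, matching the zero-centered prior.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, gammaln

from .polyagamma import sample_pg
from .sparse_prior import PrecisionState, update_precisions

log = logging.getLogger(__name__)

__all__ = [
    "McmcConfig",
    "ModelFit",
    "fit_normal",
    "fit_poisson",
    "fit_binomial",
    "fit_nbin",
    "fit_model",
    "predict_expression",
]

_PSI_CLIP = 30.0  # |log-rate| bound when exponentiating latent states


@dataclass
class McmcConfig:
    """MCMC settings shared by all samplers (single chain, no thinning)."""

    n_iter: int = 4000
    burnin: int = 2000
    seed: int = 0
    call_threshold: float = 3.0
    adapt_target: float = 0.4
    adapt_rate: float = 0.1

    def __post_init__(self):
        if not 0 <= self.burnin < self.n_iter:
            raise ValueError("require 0 <= burnin < n_iter")


@dataclass
class Hyper:
    """Hyperparameters of the proper-prior variant of each sampler.

    The defaults reproduce the fitting configuration: flat prior on the
    intercepts, Jeffreys priors on the shrinkage precisions, InvGamma(1, 1)
    on the latent variances and a flat prior on log r.  The Geweke
    correctness harness overrides them with proper choices.
    """

    mu_prec: float = 0.0
    prec_shape: float = 0.0
    prec_rate: float = 0.0
    sig_a: float = 1.0
    sig_b: float = 1.0
    logr_mu: float | None = None
    logr_sd: float | None = None


@dataclass
class ModelFit:
    """Posterior draws and run metadata produced by one sampler."""

    model: str
    beta_draws: np.ndarray  # (retained, M, K)
    mu_draws: np.ndarray  # (retained, K)
    marker_ids: list[str]
    transcript_ids: list[str]
    x_center: np.ndarray  # training column means used to center genotypes
    config: McmcConfig
    transform: str | None = None
    offsets: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    @property
    def beta_median(self) -> np.ndarray:
        return np.median(self.beta_draws, axis=0)

    @property
    def mu_median(self) -> np.ndarray:
        return np.median(self.mu_draws, axis=0)

    def called(self, threshold_sd: float | None = None) -> np.ndarray:
        from .sparse_prior import call_associations

        t = self.config.call_threshold if threshold_sd is None else threshold_sd
        return call_associations(self.beta_draws, threshold_sd=t)


# ---------------------------------------------------------------------------
# shared pieces
# ---------------------------------------------------------------------------


def _as_values(obj, kind: str):
    """Accept either a domain container or a bare array; return (values, ids)."""
    values = np.asarray(getattr(obj, "values", obj), dtype=float)
    if kind == "genotype":
        ids = getattr(obj, "marker_ids", None)
        if ids is None:
            ids = [f"m{j}" for j in range(values.shape[1])]
    else:
        ids = getattr(obj, "transcript_ids", None)
        if ids is None:
            ids = [f"t{k}" for k in range(values.shape[1])]
    return values, list(ids)


def _log_size_factors(z: np.ndarray) -> np.ndarray:
    """Log size-factor offsets, median-of-ratios by default.

    The median-of-ratios estimator resists compositional distortion: when a
    few strongly-affected transcripts dominate the library size (small K),
    total-count factors soak up part of the genetic signal and leak it into
    every other transcript as spurious association.
    """
    from .transforms import size_factors

    lib = z.sum(axis=1)
    if np.any(lib <= 0):
        raise ValueError("every sample needs a positive library size")
    return np.log(size_factors(z, "median_of_ratios"))


def _robust_trials(z: np.ndarray) -> np.ndarray:
    """Binomial denominators: median-of-ratios depth estimates (>= row maxima)."""
    from .transforms import size_factors

    f = size_factors(z, "median_of_ratios")
    nt = np.round(f * z.sum(axis=1).mean())
    return np.maximum(nt, z.max(axis=1)).astype(np.int64)


def _draw_beta_scalar_weights(xtx, x, resp, w_k, prior_diag, rng, post_scale=None):
    """Batched beta draw when the observation precision is constant per transcript.

    A_k = w_k * X'X + diag(prior_diag_k); when ``post_scale`` is given the
    inner matrix is X'X + diag(.) and the whole posterior precision is
    post_scale_k times it (the Normal model's tau_k factorization).
    """
    m, k = prior_diag.shape
    if post_scale is not None:
        inner = np.broadcast_to(xtx, (k, m, m)).copy()
        inner[:, np.arange(m), np.arange(m)] += prior_diag.T
        rhs = (x.T @ resp).T[:, :, None]  # (K, M, 1)
        mean = np.linalg.solve(inner, rhs)[:, :, 0]
        chol = np.linalg.cholesky(inner)
        zdraw = rng.standard_normal((k, m, 1))
        dev = np.linalg.solve(np.transpose(chol, (0, 2, 1)), zdraw)[:, :, 0]
        beta = mean + dev / np.sqrt(post_scale)[:, None]
        return beta.T
    a = xtx[None, :, :] * np.asarray(w_k)[:, None, None]
    a[:, np.arange(m), np.arange(m)] += prior_diag.T
    rhs = ((x.T @ resp) * np.asarray(w_k)[None, :]).T[:, :, None]
    mean = np.linalg.solve(a, rhs)[:, :, 0]
    chol = np.linalg.cholesky(a)
    zdraw = rng.standard_normal((k, m, 1))
    dev = np.linalg.solve(np.transpose(chol, (0, 2, 1)), zdraw)[:, :, 0]
    return (mean + dev).T


def _draw_beta_entry_weights(x, resp, w, prior_diag, rng):
    """Batched beta draw with per-entry precisions w (N, K): the PG models."""
    m, k = prior_diag.shape
    xw = x[None, :, :] * w.T[:, :, None]  # (K, N, M)
    a = np.matmul(x.T[None, :, :], xw)  # batched BLAS beats einsum here
    a[:, np.arange(m), np.arange(m)] += prior_diag.T
    rhs = (x.T @ (w * resp)).T[:, :, None]
    mean = np.linalg.solve(a, rhs)[:, :, 0]
    chol = np.linalg.cholesky(a)
    zdraw = rng.standard_normal((k, m, 1))
    dev = np.linalg.solve(np.transpose(chol, (0, 2, 1)), zdraw)[:, :, 0]
    return (mean + dev).T


def _draw_mu(resid_mean, total_prec, data_prec_sum, rng):
    """Conjugate normal intercept draw with optional zero-mean proper prior."""
    mean = data_prec_sum * resid_mean / total_prec
    return mean + rng.standard_normal(mean.shape) / np.sqrt(total_prec)


def _draw_sigma2(rss, n, hyper, rng):
    a = hyper.sig_a + 0.5 * n
    b = hyper.sig_b + 0.5 * rss
    return b / rng.gamma(a, 1.0, size=rss.shape)


# ---------------------------------------------------------------------------
# per-model single Gibbs sweeps (used by the fitters and the Geweke harness)
# ---------------------------------------------------------------------------


class _State:
    """Mutable sampler state; attributes depend on the model."""

    def __init__(self, **kw):
        self.__dict__.update(kw)


def _normal_sweep(x, xtx, y, st, rng, hyper: Hyper):
    n = x.shape[0]
    resp = y - st.mu[None, :]
    prior_inner = st.prec.zeta * st.prec.eta[:, None]  # tau_k factored out
    st.beta = _draw_beta_scalar_weights(
        xtx, x, resp, None, prior_inner, rng, post_scale=st.prec.tau
    )
    fitted = x @ st.beta
    resid = y - fitted
    total_prec = n * st.prec.tau + hyper.mu_prec
    st.mu = _draw_mu(resid.mean(axis=0), total_prec, n * st.prec.tau, rng)
    rss = ((resid - st.mu[None, :]) ** 2).sum(axis=0)
    st.prec = update_precisions(
        st.beta,
        st.prec,
        rng,
        prior_shape=hyper.prec_shape,
        prior_rate=hyper.prec_rate,
        tau_extra_shape=0.5 * n,
        tau_extra_rate=0.5 * rss,
    )


def _latent_gaussian_updates(x, xtx, st, rng, hyper: Hyper):
    """Shared (beta, mu, sigma2, precisions) block of the pois/bin samplers."""
    n = x.shape[0]
    resp = st.ylat - st.mu[None, :]
    prior_diag = st.prec.tau[None, :] * st.prec.zeta * st.prec.eta[:, None]
    st.beta = _draw_beta_scalar_weights(xtx, x, resp, 1.0 / st.sigma2, prior_diag, rng)
    resid = st.ylat - x @ st.beta
    data_prec = n / st.sigma2
    st.mu = _draw_mu(resid.mean(axis=0), data_prec + hyper.mu_prec, data_prec, rng)
    rss = ((resid - st.mu[None, :]) ** 2).sum(axis=0)
    st.sigma2 = _draw_sigma2(rss, n, hyper, rng)
    st.prec = update_precisions(
        st.beta, st.prec, rng, prior_shape=hyper.prec_shape, prior_rate=hyper.prec_rate
    )


def _pois_sweep(x, xtx, z, offsets, st, rng, hyper: Hyper, adapt: bool, cfg: McmcConfig):
    # Metropolis-within-Gibbs on each latent log-rate y_ik
    m_lat = st.mu[None, :] + x @ st.beta
    step = np.exp(st.log_step)
    prop = st.ylat + step * rng.standard_normal(st.ylat.shape)
    cur_rate = np.exp(np.clip(st.ylat + offsets[:, None], -_PSI_CLIP, _PSI_CLIP))
    prop_rate = np.exp(np.clip(prop + offsets[:, None], -_PSI_CLIP, _PSI_CLIP))
    logp = (
        z * (prop - st.ylat)
        - (prop_rate - cur_rate)
        - ((prop - m_lat) ** 2 - (st.ylat - m_lat) ** 2) / (2.0 * st.sigma2[None, :])
    )
    accept = np.log(rng.random(st.ylat.shape)) < logp
    st.ylat = np.where(accept, prop, st.ylat)
    st.accept_sum += accept
    st.accept_n += 1
    if adapt:
        st.log_step += cfg.adapt_rate * (accept.astype(float) - cfg.adapt_target)
    _latent_gaussian_updates(x, xtx, st, rng, hyper)


def _bin_sweep(x, xtx, z, n_trials, st, rng, hyper: Hyper):
    # Polya-Gamma augmentation makes the latent y conditionally Gaussian
    omega = sample_pg(n_trials[:, None], st.ylat, rng)
    m_lat = st.mu[None, :] + x @ st.beta
    kappa = z - n_trials[:, None] / 2.0
    prec = omega + 1.0 / st.sigma2[None, :]
    st.ylat = (kappa + m_lat / st.sigma2[None, :]) / prec + rng.standard_normal(
        z.shape
    ) / np.sqrt(prec)
    _latent_gaussian_updates(x, xtx, st, rng, hyper)


def _nbin_loglik_r(z, psi, r_row):
    # log NB(z | r, sigmoid(psi)) summed over samples, dropping r-free terms
    log1pe = np.logaddexp(0.0, psi)
    return (gammaln(z + r_row[None, :]) - gammaln(r_row[None, :]) - (z + r_row[None, :]) * log1pe).sum(
        axis=0
    )


def _nbin_sweep(x, xtx, z, offsets, st, rng, hyper: Hyper, adapt: bool, cfg: McmcConfig):
    psi = np.clip(
        st.mu[None, :] + offsets[:, None] + x @ st.beta, -_PSI_CLIP, _PSI_CLIP
    )
    omega = sample_pg(z + st.r[None, :], psi, rng)
    pseudo = (z - st.r[None, :]) / (2.0 * omega)
    resp = pseudo - st.mu[None, :] - offsets[:, None]
    prior_diag = st.prec.tau[None, :] * st.prec.zeta * st.prec.eta[:, None]
    st.beta = _draw_beta_entry_weights(x, resp, omega, prior_diag, rng)
    resid = pseudo - offsets[:, None] - x @ st.beta
    wsum = omega.sum(axis=0)
    total_prec = wsum + hyper.mu_prec
    st.mu = ((omega * resid).sum(axis=0)) / total_prec + rng.standard_normal(
        st.mu.shape
    ) / np.sqrt(total_prec)
    # random-walk Metropolis on log r_k
    psi = np.clip(
        st.mu[None, :] + offsets[:, None] + x @ st.beta, -_PSI_CLIP, _PSI_CLIP
    )
    log_r_prop = np.log(st.r) + np.exp(st.r_log_step) * rng.standard_normal(st.r.shape)
    r_prop = np.exp(np.clip(log_r_prop, -10.0, 10.0))
    ll_cur = _nbin_loglik_r(z, psi, st.r)
    ll_prop = _nbin_loglik_r(z, psi, r_prop)
    logp = ll_prop - ll_cur
    if hyper.logr_mu is not None:
        lp = lambda lr: -0.5 * ((lr - hyper.logr_mu) / hyper.logr_sd) ** 2
        logp += lp(np.log(r_prop)) - lp(np.log(st.r))
    accept = np.log(rng.random(st.r.shape)) < logp
    st.r = np.where(accept, r_prop, st.r)
    st.r_accept_sum += accept
    st.r_accept_n += 1
    if adapt:
        st.r_log_step += cfg.adapt_rate * (accept.astype(float) - cfg.adapt_target)
    st.prec = update_precisions(
        st.beta, st.prec, rng, prior_shape=hyper.prec_shape, prior_rate=hyper.prec_rate
    )


# ---------------------------------------------------------------------------
# fitters
# ---------------------------------------------------------------------------


def _prepare(x_obj, resp_obj, kind):
    x, marker_ids = _as_values(x_obj, "genotype")
    y, transcript_ids = _as_values(resp_obj, kind)
    if x.shape[0] != y.shape[0]:
        raise ValueError("genotype and expression matrices disagree on N")
    if x.shape[1] == 0 or y.shape[1] == 0:
        raise ValueError("need at least one marker and one transcript")
    center = x.mean(axis=0)
    return x - center, center, y, marker_ids, transcript_ids


def _run(model, sweep, st, cfg, n_retain_shapes, record):
    retained = cfg.n_iter - cfg.burnin
    store = {name: np.empty((retained,) + shape) for name, shape in n_retain_shapes.items()}
    t0 = time.perf_counter()
    for it in range(cfg.n_iter):
        sweep(it)
        if it >= cfg.burnin:
            record(store, it - cfg.burnin, st)
    elapsed = time.perf_counter() - t0
    log.info("%s: %d sweeps in %.1fs", model, cfg.n_iter, elapsed)
    return store, elapsed


def fit_normal(x_obj, y_obj, cfg: McmcConfig | None = None, hyper: Hyper | None = None) -> ModelFit:
    """Gibbs sampler for the Normal model on transformed expression data."""
    cfg = cfg or McmcConfig()
    hyper = hyper or Hyper()
    x, center, y, marker_ids, transcript_ids = _prepare(x_obj, y_obj, "transformed")
    if not np.all(np.isfinite(y)):
        raise ValueError("transformed expression must be finite")
    n, m = x.shape
    k = y.shape[1]
    rng = np.random.default_rng(cfg.seed)
    xtx = x.T @ x
    st = _State(beta=np.zeros((m, k)), mu=y.mean(axis=0), prec=PrecisionState.ones(m, k))

    def sweep(it):
        _normal_sweep(x, xtx, y, st, rng, hyper)

    def record(store, i, st):
        store["beta"][i] = st.beta
        store["mu"][i] = st.mu
        store["tau"][i] = st.prec.tau

    store, elapsed = _run(
        "normal", sweep, st, cfg, {"beta": (m, k), "mu": (k,), "tau": (k,)}, record
    )
    transform = getattr(y_obj, "method", None)
    return ModelFit(
        model="normal",
        beta_draws=store["beta"],
        mu_draws=store["mu"],
        marker_ids=marker_ids,
        transcript_ids=transcript_ids,
        x_center=center,
        config=cfg,
        transform=transform,
        extras={"tau_draws": store["tau"], "seconds": elapsed},
    )


def fit_poisson(x_obj, z_obj, cfg: McmcConfig | None = None, hyper: Hyper | None = None) -> ModelFit:
    """Gibbs/Metropolis sampler for the over-dispersed Poisson (Poisson-LogNormal) model."""
    cfg = cfg or McmcConfig()
    hyper = hyper or Hyper()
    x, center, z, marker_ids, transcript_ids = _prepare(x_obj, z_obj, "counts")
    _check_counts(z)
    n, m = x.shape
    k = z.shape[1]
    rng = np.random.default_rng(cfg.seed)
    xtx = x.T @ x
    offsets = _log_size_factors(z)
    ylat = np.log(z + 0.5) - offsets[:, None]
    st = _State(
        beta=np.zeros((m, k)),
        mu=ylat.mean(axis=0),
        sigma2=np.ones(k),
        prec=PrecisionState.ones(m, k),
        ylat=ylat,
        log_step=np.full((n, k), np.log(0.5)),
        accept_sum=np.zeros((n, k)),
        accept_n=0,
    )

    def sweep(it):
        _pois_sweep(x, xtx, z, offsets, st, rng, hyper, it < cfg.burnin, cfg)
        if it == cfg.burnin:  # acceptance statistics over post-adaptation sweeps only
            st.accept_sum[:] = 0.0
            st.accept_n = 0

    def record(store, i, st):
        store["beta"][i] = st.beta
        store["mu"][i] = st.mu
        store["sigma2"][i] = st.sigma2

    store, elapsed = _run(
        "pois", sweep, st, cfg, {"beta": (m, k), "mu": (k,), "sigma2": (k,)}, record
    )
    acc = st.accept_sum / max(st.accept_n, 1)
    return ModelFit(
        model="pois",
        beta_draws=store["beta"],
        mu_draws=store["mu"],
        marker_ids=marker_ids,
        transcript_ids=transcript_ids,
        x_center=center,
        config=cfg,
        offsets=offsets,
        extras={
            "sigma2_draws": store["sigma2"],
            "acceptance": acc,
            "seconds": elapsed,
        },
    )


def fit_binomial(x_obj, z_obj, cfg: McmcConfig | None = None, hyper: Hyper | None = None) -> ModelFit:
    """Gibbs sampler for the over-dispersed Binomial model (library-size denominators)."""
    cfg = cfg or McmcConfig()
    hyper = hyper or Hyper()
    x, center, z, marker_ids, transcript_ids = _prepare(x_obj, z_obj, "counts")
    _check_counts(z)
    n, m = x.shape
    k = z.shape[1]
    rng = np.random.default_rng(cfg.seed)
    xtx = x.T @ x
    n_trials = _robust_trials(z)
    if np.any(z > n_trials[:, None]):
        raise ValueError("counts exceed library sizes")  # impossible by construction
    p0 = (z + 0.5) / (n_trials[:, None] + 1.0)
    ylat = np.log(p0 / (1.0 - p0))
    st = _State(
        beta=np.zeros((m, k)),
        mu=ylat.mean(axis=0),
        sigma2=np.ones(k),
        prec=PrecisionState.ones(m, k),
        ylat=ylat,
    )

    def sweep(it):
        _bin_sweep(x, xtx, z, n_trials, st, rng, hyper)

    def record(store, i, st):
        store["beta"][i] = st.beta
        store["mu"][i] = st.mu
        store["sigma2"][i] = st.sigma2

    store, elapsed = _run(
        "bin", sweep, st, cfg, {"beta": (m, k), "mu": (k,), "sigma2": (k,)}, record
    )
    return ModelFit(
        model="bin",
        beta_draws=store["beta"],
        mu_draws=store["mu"],
        marker_ids=marker_ids,
        transcript_ids=transcript_ids,
        x_center=center,
        config=cfg,
        extras={
            "sigma2_draws": store["sigma2"],
            "n_trials": n_trials,
            "seconds": elapsed,
        },
    )


def fit_nbin(x_obj, z_obj, cfg: McmcConfig | None = None, hyper: Hyper | None = None) -> ModelFit:
    """Gibbs sampler for the Negative Binomial model with Polya-Gamma augmentation."""
    cfg = cfg or McmcConfig()
    hyper = hyper or Hyper()
    x, center, z, marker_ids, transcript_ids = _prepare(x_obj, z_obj, "counts")
    _check_counts(z)
    n, m = x.shape
    k = z.shape[1]
    rng = np.random.default_rng(cfg.seed)
    xtx = x.T @ x
    offsets = _log_size_factors(z)
    mu0 = np.log(np.maximum(z.mean(axis=0), 0.5))
    st = _State(
        beta=np.zeros((m, k)),
        mu=mu0,
        r=np.full(k, 10.0),
        prec=PrecisionState.ones(m, k),
        r_log_step=np.full(k, np.log(0.3)),
        r_accept_sum=np.zeros(k),
        r_accept_n=0,
    )
    # mu is the log-odds intercept: mean = r * exp(psi) so psi ~ log(mean / r)
    st.mu = mu0 - np.log(st.r)

    def sweep(it):
        _nbin_sweep(x, xtx, z, offsets, st, rng, hyper, it < cfg.burnin, cfg)
        if it == cfg.burnin:
            st.r_accept_sum[:] = 0.0
            st.r_accept_n = 0

    def record(store, i, st):
        store["beta"][i] = st.beta
        store["mu"][i] = st.mu
        store["r"][i] = st.r

    store, elapsed = _run(
        "nbin", sweep, st, cfg, {"beta": (m, k), "mu": (k,), "r": (k,)}, record
    )
    acc = st.r_accept_sum / max(st.r_accept_n, 1)
    return ModelFit(
        model="nbin",
        beta_draws=store["beta"],
        mu_draws=store["mu"],
        marker_ids=marker_ids,
        transcript_ids=transcript_ids,
        x_center=center,
        config=cfg,
        offsets=offsets,
        extras={"r_draws": store["r"], "acceptance": acc, "seconds": elapsed},
    )


_FITTERS = {
    "normal": fit_normal,
    "pois": fit_poisson,
    "bin": fit_binomial,
    "nbin": fit_nbin,
}


def fit_model(model: str, x_obj, resp_obj, cfg: McmcConfig | None = None) -> ModelFit:
    """Dispatch by model name ('normal', 'pois', 'bin', 'nbin')."""
    try:
        fitter = _FITTERS[model]
    except KeyError:
        raise ValueError(f"unknown model {model!r}") from None
    return fitter(x_obj, resp_obj, cfg)


def _check_counts(z: np.ndarray):
    if np.any(z < 0) or not np.allclose(z, np.round(z)):
        raise ValueError("count models need non-negative integer expression data")
    if np.any(z.sum(axis=0) == 0):
        log.warning("all-zero transcript(s) present; the intercept will absorb them")


def predict_expression(
    fit: ModelFit,
    x_new_obj,
    offsets: np.ndarray | None = None,
    n_trials: np.ndarray | None = None,
) -> np.ndarray:
    """Plug posterior-median parameters into the model mean for new genotypes.

    Returns transformed-scale predictions for the Normal model and
    expected counts for the count models.  ``offsets`` (pois/nbin) and
    ``n_trials`` (bin) describe the sequencing depth of the new samples and
    default to the average training depth.
    """
    x_new, markers = _as_values(x_new_obj, "genotype")
    if markers != fit.marker_ids and len(markers) != len(fit.marker_ids):
        raise ValueError("marker sets of fit and x_new disagree")
    xc = x_new - fit.x_center
    beta = fit.beta_median
    mu = fit.mu_median
    lin = mu[None, :] + xc @ beta
    if fit.model == "normal":
        return lin
    if fit.model == "pois":
        o = np.zeros(x_new.shape[0]) if offsets is None else np.asarray(offsets)
        s2 = np.median(fit.extras["sigma2_draws"], axis=0)
        return np.exp(np.clip(lin + o[:, None] + s2[None, :] / 2.0, -_PSI_CLIP, _PSI_CLIP))
    if fit.model == "bin":
        if n_trials is None:
            n_trials = np.full(x_new.shape[0], fit.extras["n_trials"].mean())
        return np.asarray(n_trials)[:, None] * expit(lin)
    if fit.model == "nbin":
        o = np.zeros(x_new.shape[0]) if offsets is None else np.asarray(offsets)
        r = np.median(fit.extras["r_draws"], axis=0)
        psi = np.clip(lin + o[:, None], -_PSI_CLIP, _PSI_CLIP)
        return r[None, :] * np.exp(psi)
    raise ValueError(f"unknown model {fit.model!r}")
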