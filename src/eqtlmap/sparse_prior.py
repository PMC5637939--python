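"""Shared sparse-Bayesian core: three-level shrinkage prior and Gibbs updates.

Every regression coefficient carries the prior

    beta_jk ~ N(0, (tau_k * zeta_jk * eta_j)^-1),

where tau_k is transcript-specific, eta_j marker-specific, and zeta_jk
pair-specific; each precision follows the improper Jeffreys prior p(x) ~ 1/x.
Small eta_j marks a hotspot (marker j free to influence many transcripts);
small tau_k marks a polygenic transcript.  Under this prior and a Gaussian
(or conditionally Gaussian, after augmentation) likelihood, the conditional
posterior of the coefficient vector beta_k is multivariate Normal with an
explicit mean m_k and precision A_k, and all precision conditionals are
Gamma — the whole model is sampled by plain Gibbs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

__all__ = [
    "PrecisionState",
    "BetaPosterior",
    "compute_beta_posterior",
    "sample_beta",
    "update_precisions",
    "call_associations",
]

PRECISION_MIN = 1e-12
PRECISION_MAX = 1e12


@dataclass
class PrecisionState:
    """Current values of the shrinkage precisions (tau: K, eta: M, zeta: M x K)."""

    tau: np.ndarray
    eta: np.ndarray
    zeta: np.ndarray

    def __post_init__(self):
        self.tau = np.asarray(self.tau, dtype=float)
        self.eta = np.asarray(self.eta, dtype=float)
        self.zeta = np.asarray(self.zeta, dtype=float)
        for name, arr in (("tau", self.tau), ("eta", self.eta), ("zeta", self.zeta)):
            if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
                raise ValueError(f"{name} must be strictly positive and finite")
        if self.zeta.shape != (self.eta.size, self.tau.size):
            raise ValueError("zeta must have shape (M, K)")

    @classmethod
    def ones(cls, n_markers: int, n_transcripts: int) -> "PrecisionState":
        return cls(
            tau=np.ones(n_transcripts),
            eta=np.ones(n_markers),
            zeta=np.ones((n_markers, n_transcripts)),
        )


@dataclass
class BetaPosterior:
    """Conditional posterior of beta_k: MVN with mean ``mean``, precision ``precision``."""

    mean: np.ndarray
    precision: np.ndarray
    chol: np.ndarray  # lower Cholesky factor of the precision


def _chol_with_jitter(a: np.ndarray) -> np.ndarray:
    try:
        return linalg.cholesky(a, lower=True)
    except linalg.LinAlgError:
        jitter = 1e-8 * np.eye(a.shape[0])
        return linalg.cholesky(a + jitter, lower=True)


def compute_beta_posterior(x, resp, weights, tau_k, zeta_k, eta) -> BetaPosterior:
    """Conditional posterior of one transcript's coefficient vector.

    Parameters
    ----------
    x : (N, M) array
        Mean-centered genotype matrix.
    resp : (N,) array
        The (pseudo-)response for transcript k, already de-meaned.
    weights : (N,) array or scalar
        Observation precisions: all tau_k for the Normal model (making
        A_k = tau_k (X'X + diag(zeta_k * eta))), Polya-Gamma draws for the
        augmented count models, 1/sigma_k^2 for the latent-Gaussian ones.
    tau_k, zeta_k, eta
        Shrinkage precisions entering the prior diagonal tau_k*zeta_k*eta.
    """
    x = np.asarray(x, dtype=float)
    resp = np.asarray(resp, dtype=float)
    w = np.broadcast_to(np.asarray(weights, dtype=float), resp.shape)
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(resp)) or np.any(~np.isfinite(w)):
        raise ValueError("non-finite inputs to compute_beta_posterior")
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    prior_diag = float(tau_k) * np.asarray(zeta_k, dtype=float) * np.asarray(eta, dtype=float)
    a = (x * w[:, None]).T @ x
    a[np.diag_indices_from(a)] += prior_diag
    rhs = x.T @ (w * resp)
    chol = _chol_with_jitter(a)
    mean = linalg.cho_solve((chol, True), rhs)
    return BetaPosterior(mean=mean, precision=a, chol=chol)


def sample_beta(bp: BetaPosterior, rng) -> np.ndarray:
    """One MVN(m_k, A_k^-1) draw via the stored Cholesky factor of A_k."""
    z = rng.standard_normal(bp.mean.shape[0])
    return bp.mean + linalg.solve_triangular(bp.chol, z, lower=True, trans="T")


def update_precisions(
    beta: np.ndarray,
    state: PrecisionState,
    rng,
    prior_shape: float = 0.0,
    prior_rate: float = 0.0,
    tau_extra_shape: np.ndarray | float = 0.0,
    tau_extra_rate: np.ndarray | float = 0.0,
) -> PrecisionState:
    """Gibbs-update all shrinkage precisions given the coefficient matrix.

    The Jeffreys conditionals are, in shape-rate parameterization,

        tau_k  ~ Gamma(M/2, 1/2 sum_j zeta_jk eta_j beta_jk^2)
        eta_j  ~ Gamma(K/2, 1/2 sum_k tau_k zeta_jk beta_jk^2)
        zeta_jk~ Gamma(1/2,  1/2 tau_k eta_j beta_jk^2)

    updated in that order (each conditional sees the freshest neighbours).
    ``prior_shape``/``prior_rate`` add a proper Gamma(a0, b0) hyperprior on
    every precision (0 recovers Jeffreys); ``tau_extra_*`` add the residual
    likelihood contribution when tau_k doubles as the Normal model's noise
    precision.  Zero rates (a coefficient row/column exactly zero) are floored
    at 1e-12 with a warning; draws are clipped to [1e-12, 1e12].
    """
    b2 = np.asarray(beta, dtype=float) ** 2
    m, k = b2.shape
    floored = False

    def _draw(shape, rate, size):
        nonlocal floored
        rate = np.asarray(rate, dtype=float)
        if np.any(rate <= 0):
            floored = True
            rate = np.maximum(rate, PRECISION_MIN)
        g = rng.gamma(shape, 1.0 / rate, size=size)
        return np.clip(g, PRECISION_MIN, PRECISION_MAX)

    tau_rate = 0.5 * np.einsum("jk,jk,j->k", state.zeta, b2, state.eta) + prior_rate
    tau = _draw(m / 2.0 + prior_shape + tau_extra_shape, tau_rate + tau_extra_rate, k)

    eta_rate = 0.5 * np.einsum("jk,jk,k->j", state.zeta, b2, tau) + prior_rate
    eta = _draw(k / 2.0 + prior_shape, eta_rate, m)

    zeta_rate = 0.5 * b2 * tau[None, :] * eta[:, None] + prior_rate
    zeta = _draw(0.5 + prior_shape, zeta_rate, (m, k))

    if floored:
        warnings.warn(
            "zero Gamma rate in precision update (exactly-zero coefficients); "
            "floored at 1e-12",
            RuntimeWarning,
            stacklevel=2,
        )
    return PrecisionState(tau=tau, eta=eta, zeta=zeta)


def call_associations(beta_draws: np.ndarray, threshold_sd: float = 3.0) -> np.ndarray:
    """Post-hoc association calls from retained posterior draws of B.

    Entry (j, k) is called when its posterior median exceeds ``threshold_sd``
    times its own posterior standard deviation — a per-entry signal-to-noise
    rule, roughly "the credible interval sits clear of zero".  Under the
    shrinkage prior, null coefficients collapse onto zero with sign-symmetric
    draws (median within Monte-Carlo error of zero), so they are never called;
    a coefficient the data supports keeps a median far outside its own
    posterior spread.  Degenerate all-identical draws are never called.
    """
    draws = np.asarray(beta_draws, dtype=float)
    if draws.ndim != 3:
        raise ValueError("beta_draws must have shape (draws, M, K)")
    if draws.shape[0] < 50:
        raise ValueError("need at least 50 retained draws to call associations")
    med = np.median(draws, axis=0)
    sd = draws.std(axis=0)
    out = np.zeros_like(med, dtype=bool)
    ok = sd > 0
    out[ok] = np.abs(med[ok]) > threshold_sd * sd[ok]
    return out
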