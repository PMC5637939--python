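"""Read-count transformations feeding the Normal model.

An RNA-seq sample is viewed as a multinomial experiment: the library's reads
are distributed over K transcripts.  Laplace (additive) smoothing converts a
row of counts into strictly positive mapping probabilities,

    p_ik = (z_ik + c) / (sum_k z_ik + c K),

which are then mapped to the real line with the arcsin (y = arcsin sqrt p) or
logit (y = log p/(1-p)) transformations.  The classical log, Box-Cox and Blom
transformations operate directly on the counts.  All transforms are
deterministic, column-order preserving, and use natural logarithms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

log = logging.getLogger(__name__)

__all__ = [
    "SmoothedMatrix",
    "TransformedMatrix",
    "size_factors",
    "laplace_smooth",
    "proportion_transform",
    "log_transform",
    "boxcox_transform",
    "blom_transform",
    "transform_counts",
]

TRANSFORMS = ("none", "log", "boxcox", "blom", "arcsin", "logit")


@dataclass
class SmoothedMatrix:
    """N x K matrix of smoothed per-sample transcript proportions."""

    probs: np.ndarray
    smoothing_constant: float = 1.0

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if np.any(self.probs <= 0) or np.any(self.probs >= 1):
            raise ValueError("smoothed probabilities must lie strictly in (0, 1)")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("rows of a SmoothedMatrix must sum to 1")


@dataclass
class TransformedMatrix:
    """Real-valued N x K expression matrix plus the transform that produced it."""

    values: np.ndarray
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("transformed values must be finite")


def _counts_array(z) -> np.ndarray:
    values = getattr(z, "values", z)
    return np.asarray(values, dtype=float)


def size_factors(z, method: str = "total_count") -> np.ndarray:
    """Per-sample scaling factors absorbing sequencing-depth differences.

    ``total_count`` factors are library sizes rescaled to mean 1;
    ``median_of_ratios`` is the DESeq-style estimator (median over
    all-positive transcripts of the ratio to the per-transcript geometric
    mean), rescaled to geometric mean 1.
    """
    v = _counts_array(z)
    lib = v.sum(axis=1)
    if np.any(lib <= 0):
        raise ValueError("every sample must have a positive library size")
    if method == "total_count":
        return lib / lib.mean()
    if method == "median_of_ratios":
        positive = np.all(v > 0, axis=0)
        if not positive.any():
            warnings.warn(
                "no transcript with all-positive counts; falling back to total_count",
                RuntimeWarning,
                stacklevel=2,
            )
            return lib / lib.mean()
        sub = v[:, positive]
        log_geo = np.mean(np.log(sub), axis=0)
        f = np.exp(np.median(np.log(sub) - log_geo, axis=1))
        return f / np.exp(np.mean(np.log(f)))
    raise ValueError(f"unknown size-factor method {method!r}")


def laplace_smooth(z, c: float = 1.0, factors: np.ndarray | None = None) -> SmoothedMatrix:
    """Additive smoothing of counts to strictly-positive row-stochastic proportions.

    Each smoothed entry lies between the empirical proportion z_ik / sum_k z_ik
    and the uniform 1/K; larger ``c`` (or smaller libraries) pulls toward 1/K.
    Optional ``factors`` divide the counts per sample before smoothing.
    """
    if c <= 0:
        raise ValueError("smoothing constant c must be > 0")
    v = _counts_array(z)
    if factors is not None:
        v = v / np.asarray(factors, dtype=float)[:, None]
    n, k = v.shape
    probs = (v + c) / (v.sum(axis=1, keepdims=True) + c * k)
    return SmoothedMatrix(probs=probs, smoothing_constant=c)


def proportion_transform(p: SmoothedMatrix, method: str) -> TransformedMatrix:
    """arcsin (arcsin sqrt p) or logit (log p/(1-p)) map of smoothed proportions."""
    probs = p.probs if isinstance(p, SmoothedMatrix) else np.asarray(p, dtype=float)
    if np.any(probs <= 0) or np.any(probs >= 1):
        raise ValueError("proportions must lie strictly in (0, 1)")
    if method == "arcsin":
        y = np.arcsin(np.sqrt(probs))
    elif method == "logit":
        y = special.logit(probs)
    else:
        raise ValueError(f"unknown proportion transform {method!r}")
    c = p.smoothing_constant if isinstance(p, SmoothedMatrix) else None
    return TransformedMatrix(values=y, method=method, params={"smoothing_constant": c})


def log_transform(z, pseudo_count: float = 1.0) -> TransformedMatrix:
    """Natural log of counts after adding a pseudo-count (default 1)."""
    if pseudo_count <= 0:
        raise ValueError("pseudo_count must be > 0")
    v = _counts_array(z)
    return TransformedMatrix(
        values=np.log(v + pseudo_count), method="log", params={"pseudo_count": pseudo_count}
    )


def _boxcox_apply(x: np.ndarray, lam: float) -> np.ndarray:
    if abs(lam) < 1e-12:
        return np.log(x)
    return (x**lam - 1.0) / lam


def boxcox_transform(z, bracket: tuple[float, float] = (-2.0, 2.0)) -> TransformedMatrix:
    """One-parameter Box-Cox of z+1, with lambda fit per transcript.

    lambda_k maximizes the profile log-likelihood of the Box-Cox family on
    the pseudo-counted column; the lambda=0 limit reproduces log(z+1)
    exactly.  Constant columns have no defined lambda and yield zeros.
    """
    v = _counts_array(z) + 1.0
    n, k = v.shape
    out = np.empty_like(v)
    lambdas = np.full(k, np.nan)
    for j in range(k):
        col = v[:, j]
        if np.ptp(col) == 0:
            warnings.warn(
                f"constant column {j}: Box-Cox lambda undefined, emitting zeros",
                RuntimeWarning,
                stacklevel=2,
            )
            out[:, j] = 0.0
            continue
        res = optimize.minimize_scalar(
            lambda lam: -stats.boxcox_llf(lam, col),
            bounds=bracket,
            method="bounded",
        )
        lam = float(res.x)
        lambdas[j] = lam
        out[:, j] = _boxcox_apply(col, lam)
    return TransformedMatrix(values=out, method="boxcox", params={"lambda": lambdas})


def blom_transform(z) -> TransformedMatrix:
    """Rank-based normal scores y_i = Phi^-1((r_i - 3/8) / (N + 1/4)).

    Ties receive average ranks, so a fully constant column maps to zeros.
    Output depends on the counts only through their within-column ranks.
    """
    v = _counts_array(z)
    n = v.shape[0]
    if n < 2:
        raise ValueError("Blom transform requires at least 2 samples")
    ranks = stats.rankdata(v, axis=0, method="average")
    y = special.ndtri((ranks - 3.0 / 8.0) / (n + 0.25))
    return TransformedMatrix(values=y, method="blom", params={"offset": 3.0 / 8.0})


def transform_counts(
    z,
    method: str,
    *,
    pseudo_count: float = 1.0,
    smoothing_constant: float = 1.0,
    normalize: bool = False,
) -> TransformedMatrix:
    """Dispatch a named transform; the entry point used by the CLI and CV."""
    if method == "none":
        return TransformedMatrix(values=_counts_array(z), method="none")
    if method == "log":
        return log_transform(z, pseudo_count)
    if method == "boxcox":
        return boxcox_transform(z)
    if method == "blom":
        return blom_transform(z)
    if method in ("arcsin", "logit"):
        factors = size_factors(z, "total_count") if normalize else None
        return proportion_transform(laplace_smooth(z, smoothing_constant, factors), method)
    raise ValueError(f"unknown transform {method!r}")
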