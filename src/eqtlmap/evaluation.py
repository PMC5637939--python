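"""Benchmark metrics (MCC, RMSE among true positives, Lin's CCC) and
Monte Carlo cross-validation.

MCC scores association *detection* against a known truth; the RMSE measures
effect-size *estimation* among the true positives after both coefficient
matrices are rescaled by their own largest absolute entry; CCC scores
*predictive* agreement between predicted and observed expression on held-out
samples, which is how models are compared when no truth is available.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .models import McmcConfig, fit_model, predict_expression
from .transforms import transform_counts

log = logging.getLogger(__name__)

__all__ = [
    "BenchmarkResult",
    "CVResult",
    "confusion",
    "mcc",
    "rmse_true_positives",
    "ccc",
    "benchmark",
    "monte_carlo_cv",
]


@dataclass
class BenchmarkResult:
    mcc: float
    rmse_tp: float  # NaN when there are no true positives
    tpr: float
    ppv: float
    n_tp: int
    n_fp: int
    n_tn: int
    n_fn: int


@dataclass
class CVResult:
    ccc_per_repeat: list[float] = field(default_factory=list)
    n_called_per_repeat: list[int] = field(default_factory=list)

    @property
    def mean_ccc(self) -> float:
        return float(np.mean(self.ccc_per_repeat)) if self.ccc_per_repeat else math.nan


def confusion(called: np.ndarray, truth_nonzero: np.ndarray):
    called = np.asarray(called, dtype=bool)
    truth = np.asarray(truth_nonzero, dtype=bool)
    if called.shape != truth.shape:
        raise ValueError("called and truth shapes disagree")
    tp = int((called & truth).sum())
    fp = int((called & ~truth).sum())
    fn = int((~called & truth).sum())
    tn = int((~called & ~truth).sum())
    return tp, fp, tn, fn


def mcc(called: np.ndarray, truth_nonzero: np.ndarray) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0."""
    tp, fp, tn, fn = confusion(called, truth_nonzero)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def rmse_true_positives(
    b_est: np.ndarray, b_true: np.ndarray, called: np.ndarray, truth_nonzero: np.ndarray
) -> float:
    """RMSE between max-abs-normalized coefficient matrices over the true positives.

    Both matrices are divided by their own largest |entry| first, so a global
    gain mismatch between estimation scale and truth scale does not count as
    error.  Returns NaN when there is no true positive.
    """
    b_est = np.asarray(b_est, dtype=float)
    b_true = np.asarray(b_true, dtype=float)
    tp_mask = np.asarray(called, dtype=bool) & np.asarray(truth_nonzero, dtype=bool)
    if not tp_mask.any():
        return math.nan
    e = b_est / np.max(np.abs(b_est)) if np.max(np.abs(b_est)) > 0 else b_est
    t = b_true / np.max(np.abs(b_true)) if np.max(np.abs(b_true)) > 0 else b_true
    return float(np.sqrt(np.mean((e[tp_mask] - t[tp_mask]) ** 2)))


def ccc(a, b) -> float:
    """Lin's concordance correlation coefficient with population (1/n) variances."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size or a.size < 2:
        raise ValueError("ccc needs two equal-length vectors of length >= 2")
    va = a.var()
    vb = b.var()
    if va == 0 and vb == 0:
        warnings.warn("both inputs constant: CCC undefined, returning 0", RuntimeWarning)
        return 0.0
    cov = np.mean((a - a.mean()) * (b - b.mean()))
    return float(2.0 * cov / (va + vb + (a.mean() - b.mean()) ** 2))


def benchmark(fit, truth, threshold_sd: float | None = None) -> BenchmarkResult:
    """Score a ModelFit against a SimulationTruth (detection + estimation)."""
    called = fit.called(threshold_sd)
    truth_nz = truth.nonzero if hasattr(truth, "nonzero") else np.asarray(truth) != 0
    tp, fp, tn, fn = confusion(called, truth_nz)
    b_true = truth.b_true if hasattr(truth, "b_true") else np.asarray(truth)
    return BenchmarkResult(
        mcc=mcc(called, truth_nz),
        rmse_tp=rmse_true_positives(fit.beta_median, b_true, called, truth_nz),
        tpr=tp / (tp + fn) if tp + fn else math.nan,
        ppv=tp / (tp + fp) if tp + fp else math.nan,
        n_tp=tp,
        n_fp=fp,
        n_tn=tn,
        n_fn=fn,
    )


def monte_carlo_cv(
    x_obj,
    z_obj,
    model: str,
    transform: str = "none",
    repeats: int = 10,
    ratio: float = 0.75,
    seed: int = 0,
    cfg: McmcConfig | None = None,
) -> CVResult:
    """Monte Carlo cross-validation: random 3:1 train/validation splits.

    Each repeat fits the model on the training samples and scores CCC between
    predicted and observed expression on the validation samples, pooled over
    all entries.  The Normal model is compared on the transformed scale (the
    transform is recomputed within each split); count models are compared on
    the log1p scale to keep CCC stable across sequencing depths.
    """
    x = np.asarray(getattr(x_obj, "values", x_obj))
    z = np.asarray(getattr(z_obj, "values", z_obj))
    n = x.shape[0]
    n_train = int(round(ratio * n))
    if n_train < 2 or n - n_train < 2:
        raise ValueError("not enough samples for a train/validation split")
    rng = np.random.default_rng(seed)
    result = CVResult()
    for rep in range(repeats):
        perm = rng.permutation(n)
        tr, va = perm[:n_train], perm[n_train:]
        fit_seed = int(rng.integers(2**31 - 1))
        run_cfg = cfg or McmcConfig()
        run_cfg = McmcConfig(
            n_iter=run_cfg.n_iter,
            burnin=run_cfg.burnin,
            seed=fit_seed,
            call_threshold=run_cfg.call_threshold,
        )
        try:
            if model == "normal":
                y_tr = transform_counts(z[tr], transform)
                y_va = transform_counts(z[va], transform)
                fit = fit_model("normal", x[tr], y_tr, run_cfg)
                pred = predict_expression(fit, x[va])
                score = ccc(pred, y_va.values)
            else:
                fit = fit_model(model, x[tr], z[tr], run_cfg)
                lib_va = z[va].sum(axis=1)
                offsets = np.log(lib_va / z[tr].sum(axis=1).mean())
                pred = predict_expression(fit, x[va], offsets=offsets, n_trials=lib_va)
                score = ccc(np.log1p(pred), np.log1p(z[va]))
        except Exception as exc:  # pragma: no cover - defensive
            log.warning("CV repeat %d failed: %s", rep, exc)
            continue
        result.ccc_per_repeat.append(score)
        result.n_called_per_repeat.append(int(fit.called().sum()))
    return result
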