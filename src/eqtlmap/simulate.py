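"""Template-style simulator for paired genotype / read-count datasets.

The generator produces (X, Z, B_true) triplets mimicking the statistical
structure of population-cohort data: genotypes are Hardy-Weinberg draws at
uniformly distributed minor-allele frequencies; per-gene baseline expression
is log-normal with Gamma-distributed Negative Binomial dispersions; effect
magnitudes are Exponential with random signs and act multiplicatively on the
NB mean through exp(x . beta) with mean-centered genotypes, so beta lives on
the log scale used by the count models.  Association patterns include
hotspots (one marker hitting ~10% of transcripts) and polygenic transcripts
(one transcript hit by ~10% of markers).  Two optional noise mechanisms
contaminate the data: multiplicative expression outliers (x0.1 or x10) and
genotype resampling.  Everything is a pure function of the seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .data import CountMatrix, GenotypeMatrix, save_counts, save_genotypes

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_coefficients",
    "simulate_genotypes",
    "simulate_counts",
    "simulate_dataset",
    "simulate_from_model",
]


@dataclass
class SimulationConfig:
    """Study-design knobs of the simulator (defaults: M=100 markers, K=1000 genes)."""

    n_samples: int = 250
    n_markers: int = 100
    n_transcripts: int = 1000
    n_assoc: int = 50
    n_hotspots: int = 0
    n_polygenic: int = 0
    effect_rate: float = 2.0  # Exponential rate of |beta|; mean effect = 1/rate
    effect_max: float = math.log(4.0)  # truncation: at most 4-fold change per allele
    maf_range: tuple[float, float] = (0.05, 0.5)
    nb_mean_log_mu: float = math.log(100.0)
    nb_mean_log_sd: float = 1.0
    nb_dispersion_shape: float = 2.0
    nb_dispersion_rate: float = 0.2
    overdispersed: bool = True
    noise_expr: float = 0.0
    noise_geno: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("noise_expr", "noise_geno"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("effect_rate", "effect_max", "nb_dispersion_shape", "nb_dispersion_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.nb_mean_log_sd < 0:
            raise ValueError("nb_mean_log_sd must be >= 0")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be a sub-interval of (0, 0.5]")


@dataclass
class SimulationTruth:
    """Ground-truth coefficients and the planted association pattern."""

    b_true: np.ndarray  # (M, K)
    hotspot_markers: list[int] = field(default_factory=list)
    polygenic_transcripts: list[int] = field(default_factory=list)
    config: SimulationConfig | None = None

    @property
    def nonzero(self) -> np.ndarray:
        return self.b_true != 0.0

    def to_json(self, path) -> None:
        payload = {
            "b_true_nonzero": [
                [int(j), int(k), float(self.b_true[j, k])]
                for j, k in np.argwhere(self.b_true != 0.0)
            ],
            "shape": list(self.b_true.shape),
            "hotspot_markers": [int(j) for j in self.hotspot_markers],
            "polygenic_transcripts": [int(k) for k in self.polygenic_transcripts],
            "config": asdict(self.config) if self.config else None,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        payload = json.loads(Path(path).read_text())
        b = np.zeros(payload["shape"])
        for j, k, v in payload["b_true_nonzero"]:
            b[j, k] = v
        cfg = payload.get("config")
        return cls(
            b_true=b,
            hotspot_markers=payload["hotspot_markers"],
            polygenic_transcripts=payload["polygenic_transcripts"],
            config=SimulationConfig(**{**cfg, "maf_range": tuple(cfg["maf_range"])}) if cfg else None,
        )


def simulate_coefficients(cfg: SimulationConfig, rng) -> SimulationTruth:
    """Plant the sparse coefficient matrix: hotspots, polygenic transcripts, background.

    Each hotspot marker hits ceil(0.1 K) random transcripts; each polygenic
    transcript is hit by ceil(0.1 M) random markers; the remaining
    ``n_assoc`` associations land uniformly at random without replacement.
    Magnitudes are iid Exponential(effect_rate) truncated at ``effect_max``
    (per-allele fold changes stay within the range reported for strong
    eQTLs, and no single gene can swamp the simulated library), with
    independent +/- signs.
    """
    m, k = cfg.n_markers, cfg.n_transcripts
    mask = np.zeros((m, k), dtype=bool)
    hot = list(rng.choice(m, size=cfg.n_hotspots, replace=False)) if cfg.n_hotspots else []
    poly = (
        list(rng.choice(k, size=cfg.n_polygenic, replace=False)) if cfg.n_polygenic else []
    )
    per_hot = math.ceil(0.1 * k)
    per_poly = math.ceil(0.1 * m)
    budget = cfg.n_assoc + cfg.n_hotspots * per_hot + cfg.n_polygenic * per_poly
    if budget > m * k:
        raise ValueError("association budget exceeds M*K")
    for j in hot:
        mask[j, rng.choice(k, size=per_hot, replace=False)] = True
    for t in poly:
        mask[rng.choice(m, size=per_poly, replace=False), t] = True
    free = np.flatnonzero(~mask.ravel())
    extra = rng.choice(free, size=min(cfg.n_assoc, free.size), replace=False)
    mask.ravel()[extra] = True
    b = np.zeros((m, k))
    nnz = int(mask.sum())
    # inverse-CDF draw from the Exponential truncated to (0, effect_max]
    u = rng.random(nnz)
    magnitudes = -np.log1p(-u * (-np.expm1(-cfg.effect_rate * cfg.effect_max))) / cfg.effect_rate
    signs = rng.choice((-1.0, 1.0), size=nnz)
    b[mask] = magnitudes * signs
    return SimulationTruth(b_true=b, hotspot_markers=hot, polygenic_transcripts=poly, config=cfg)


def simulate_genotypes(cfg: SimulationConfig, rng) -> GenotypeMatrix:
    """Hardy-Weinberg genotypes: per-marker MAF ~ U(maf_range), dosage ~ Binomial(2, maf)."""
    lo, hi = cfg.maf_range
    maf = rng.uniform(lo, hi, size=cfg.n_markers)
    x = rng.binomial(2, maf[None, :], size=(cfg.n_samples, cfg.n_markers))
    if cfg.noise_geno > 0:
        flip = rng.random(x.shape) < cfg.noise_geno
        x = np.where(flip, rng.binomial(2, np.broadcast_to(maf, x.shape)), x)
    return GenotypeMatrix(
        values=x,
        sample_ids=[f"s{i}" for i in range(cfg.n_samples)],
        marker_ids=[f"m{j}" for j in range(cfg.n_markers)],
    )


def simulate_counts(
    x: GenotypeMatrix, truth: SimulationTruth, cfg: SimulationConfig, rng
) -> CountMatrix:
    """Negative Binomial (or Poisson) read counts driven by X and B_true."""
    xv = np.asarray(getattr(x, "values", x), dtype=float)
    b = truth.b_true
    if xv.shape[1] != b.shape[0]:
        raise ValueError("genotype and coefficient shapes disagree")
    xc = xv - xv.mean(axis=0)
    base = rng.lognormal(cfg.nb_mean_log_mu, cfg.nb_mean_log_sd, size=cfg.n_transcripts)
    mean = base[None, :] * np.exp(xc @ b)
    if np.any(mean > 1e9):
        raise ValueError("simulated mean count exceeds 1e9; use smaller effect sizes")
    if cfg.overdispersed:
        phi = rng.gamma(cfg.nb_dispersion_shape, 1.0 / cfg.nb_dispersion_rate, size=cfg.n_transcripts)
        p = phi[None, :] / (phi[None, :] + mean)
        z = rng.negative_binomial(phi[None, :], p)
    else:
        z = rng.poisson(mean)
    if cfg.noise_expr > 0:
        outlier = rng.random(z.shape) < cfg.noise_expr
        factor = rng.choice((0.1, 10.0), size=z.shape)
        z = np.where(outlier, np.round(z * factor), z).astype(np.int64)
    return CountMatrix(
        values=z,
        sample_ids=[f"s{i}" for i in range(xv.shape[0])],
        transcript_ids=[f"t{k}" for k in range(cfg.n_transcripts)],
    )


def simulate_dataset(cfg: SimulationConfig, out_dir=None):
    """Compose coefficients, genotypes and counts; optionally persist to disk.

    Writes genotypes.tsv, counts.tsv and truth.json when ``out_dir`` is given.
    Fully determined by ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    truth = simulate_coefficients(cfg, rng)
    x = simulate_genotypes(cfg, rng)
    z = simulate_counts(x, truth, cfg, rng)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_genotypes(x, out / "genotypes.tsv")
        save_counts(z, out / "counts.tsv")
        truth.to_json(out / "truth.json")
    return x, z, truth


def simulate_from_model(
    model: str,
    x: GenotypeMatrix,
    b_true: np.ndarray,
    rng,
    mu: np.ndarray | None = None,
    sigma: float = 0.5,
    r_disp: float = 10.0,
    lib_size: int = 20000,
    noise_sd: float = 0.1,
):
    """Draw expression data from one of the four fitted model families itself.

    Used for correctly-specified recovery checks: ``normal`` returns a real
    matrix X B + noise; ``pois``/``bin``/``nbin`` return integer counts from
    the exact generative process each sampler assumes.  ``mu`` defaults to a
    baseline of log 100 (count models) or 0 (normal).
    """
    xv = np.asarray(getattr(x, "values", x), dtype=float)
    xc = xv - xv.mean(axis=0)
    n = xv.shape[0]
    k = b_true.shape[1]
    lin = xc @ b_true
    if model == "normal":
        mu = np.zeros(k) if mu is None else mu
        return mu[None, :] + lin + noise_sd * rng.standard_normal((n, k))
    if model == "pois":
        mu = np.full(k, math.log(100.0)) if mu is None else mu
        ylat = mu[None, :] + lin + sigma * rng.standard_normal((n, k))
        return rng.poisson(np.exp(np.clip(ylat, -30, 30)))
    if model == "bin":
        mu = np.full(k, math.log(100.0 / lib_size)) if mu is None else mu
        ylat = mu[None, :] + lin + sigma * rng.standard_normal((n, k))
        p = 1.0 / (1.0 + np.exp(-ylat))
        return rng.binomial(lib_size, p)
    if model == "nbin":
        mu = np.full(k, math.log(100.0 / r_disp)) if mu is None else mu
        psi = np.clip(mu[None, :] + lin, -30, 30)
        mean = r_disp * np.exp(psi)
        p = r_disp / (r_disp + mean)
        return rng.negative_binomial(r_disp, p)
    raise ValueError(f"unknown model {model!r}")
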