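"""Genotype/count containers, file IO and cohort-level filters.

Matrices are stored samples-by-features on disk, tab-separated, UTF-8, no
quoting; the first header cell is literally ``sample_id``.  Genotypes use
additive minor-allele coding: each entry is the number of minor alleles
(0, 1 or 2) carried by a sample at a bi-allelic locus.  Genotypes may also be
read from a VCF, in which case ALT-allele dosages are folded to minor-allele
dosages whenever the ALT allele is the major one.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "CountMatrix",
    "load_genotypes",
    "load_counts",
    "save_genotypes",
    "save_counts",
    "filter_markers",
    "filter_transcripts",
    "write_associations",
]


class ValidationError(ValueError):
    """Input data violates a domain invariant."""


class EmptyResultError(ValidationError):
    """A filter removed every marker or transcript."""


def _check_unique(ids, what):
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate {what} identifiers")


@dataclass
class GenotypeMatrix:
    """N x M matrix of minor-allele dosages in {0, 1, 2}."""

    values: np.ndarray
    sample_ids: list[str]
    marker_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValidationError("genotype matrix must be 2-dimensional")
        if not np.isin(self.values, (0, 1, 2)).all():
            bad = np.argwhere(~np.isin(self.values, (0, 1, 2)))[0]
            raise ValidationError(
                f"genotype entry outside {{0,1,2}} at sample "
                f"{self.sample_ids[bad[0]]!r}, marker {self.marker_ids[bad[1]]!r}"
            )
        self.values = self.values.astype(np.int64)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.marker_ids = [str(m) for m in self.marker_ids]
        n, m = self.values.shape
        if len(self.sample_ids) != n or len(self.marker_ids) != m:
            raise ValidationError("identifier lengths do not match matrix shape")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.marker_ids, "marker")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    @property
    def maf(self) -> np.ndarray:
        """Minor-allele frequency per marker, folded to [0, 0.5]."""
        freq = self.values.mean(axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)


@dataclass
class CountMatrix:
    """N x K matrix of non-negative integer read counts."""

    values: np.ndarray
    sample_ids: list[str]
    transcript_ids: list[str]

    def __post_init__(self):
        arr = np.asarray(self.values)
        if arr.ndim != 2:
            raise ValidationError("count matrix must be 2-dimensional")
        if not np.issubdtype(arr.dtype, np.integer):
            rounded = np.round(arr.astype(float))
            if not np.allclose(arr.astype(float), rounded, atol=1e-9):
                raise ValidationError("counts must be integral")
            arr = rounded
        if (arr < 0).any():
            raise ValidationError("counts must be non-negative")
        self.values = arr.astype(np.int64)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.transcript_ids = [str(t) for t in self.transcript_ids]
        n, k = self.values.shape
        if len(self.sample_ids) != n or len(self.transcript_ids) != k:
            raise ValidationError("identifier lengths do not match matrix shape")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.transcript_ids, "transcript")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_transcripts(self) -> int:
        return self.values.shape[1]

    @property
    def library_sizes(self) -> np.ndarray:
        return self.values.sum(axis=1)


def _read_matrix_tsv(path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype_backend="numpy_nullable")
    except pd.errors.ParserError as exc:
        raise ValidationError(f"malformed TSV {path}: {exc}") from exc
    if df.index.name is None:
        raise ValidationError(f"{path}: missing sample_id header column")
    return df

def load_genotypes(path, format: str = "tsv") -> GenotypeMatrix:
    """Load a genotype matrix from TSV (dosages) or VCF (GT fields).

    VCF records that are not bi-allelic SNVs are skipped with a warning;
    missing genotypes are imputed to the rounded per-marker mean dosage, and
    ALT dosages are flipped (0 <-> 2) at markers where ALT is the major allele
    so entries always count the minor allele.
    """
    if format == "tsv":
        df = _read_matrix_tsv(path)
        values = df.to_numpy()
        if pd.isna(values.astype(object)).any():
            raise ValidationError(f"{path}: missing genotype entries in TSV")
        return GenotypeMatrix(
            values=np.asarray(df, dtype=float),
            sample_ids=list(df.index.astype(str)),
            marker_ids=list(df.columns.astype(str)),
        )
    if format == "vcf":
        return _load_genotypes_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _load_genotypes_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    marker_ids: list[str] = []
    columns: list[np.ndarray] = []
    n_skipped = 0
    n_imputed = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        dosage = np.empty(len(samples))
        missing = np.zeros(len(samples), dtype=bool)
        for i, gt in enumerate(var.genotypes):
            alleles = [a for a in gt[:-1] if a is not None and a >= 0]
            if len(alleles) < 2:
                missing[i] = True
            else:
                dosage[i] = sum(1 for a in alleles[:2] if a > 0)
        if missing.all():
            n_skipped += 1
            continue
        if missing.any():
            n_imputed += int(missing.sum())
            dosage[missing] = np.round(dosage[~missing].mean())
        if dosage[~missing].mean() / 2.0 > 0.5:
            dosage = 2.0 - dosage  # ALT is the major allele: fold to minor
        marker_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        columns.append(dosage)
    vcf.close()
    if n_skipped:
        log.warning("skipped %d non-bi-allelic or all-missing VCF records", n_skipped)
    if n_imputed:
        log.warning("imputed %d missing genotypes to the rounded marker mean", n_imputed)
    if not columns:
        raise ValidationError(f"{path}: no usable bi-allelic records")
    return GenotypeMatrix(
        values=np.column_stack(columns), sample_ids=samples, marker_ids=marker_ids
    )


def load_counts(path) -> CountMatrix:
    """Load a read-count matrix from TSV (samples x transcripts)."""
    df = _read_matrix_tsv(path)
    try:
        values = np.asarray(df, dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{path}: non-numeric count entry: {exc}") from exc
    if np.isnan(values).any():
        raise ValidationError(f"{path}: missing count entries")
    return CountMatrix(
        values=values,
        sample_ids=list(df.index.astype(str)),
        transcript_ids=list(df.columns.astype(str)),
    )


def _write_matrix(values, rows, cols, path):
    df = pd.DataFrame(values, index=pd.Index(rows, name="sample_id"), columns=cols)
    df.to_csv(path, sep="\t")


def save_genotypes(g: GenotypeMatrix, path) -> None:
    _write_matrix(g.values, g.sample_ids, g.marker_ids, path)


def save_counts(z: CountMatrix, path) -> None:
    _write_matrix(z.values, z.sample_ids, z.transcript_ids, path)


def filter_markers(g: GenotypeMatrix, min_maf: float = 0.05) -> GenotypeMatrix:
    """Retain markers with folded MAF strictly greater than ``min_maf``."""
    if not 0 <= min_maf < 0.5:
        raise ValueError("min_maf must lie in [0, 0.5)")
    keep = g.maf > min_maf
    if not keep.any():
        raise EmptyResultError(f"no marker has MAF > {min_maf}")
    return GenotypeMatrix(
        values=g.values[:, keep],
        sample_ids=g.sample_ids,
        marker_ids=[m for m, k in zip(g.marker_ids, keep) if k],
    )


def filter_transcripts(z: CountMatrix, min_mean: float = 10.0) -> CountMatrix:
    """Drop transcripts averaging fewer than ``min_mean`` reads across samples."""
    if min_mean < 0:
        raise ValueError("min_mean must be >= 0")
    keep = z.values.mean(axis=0) >= min_mean
    if not keep.any():
        raise EmptyResultError(f"no transcript has mean count >= {min_mean}")
    return CountMatrix(
        values=z.values[:, keep],
        sample_ids=z.sample_ids,
        transcript_ids=[t for t, k in zip(z.transcript_ids, keep) if k],
    )


def write_associations(fit, out_dir, credible_level: float = 0.95, full: bool = True):
    """Summarize posterior draws of B into an association table on disk.

    Writes ``associations.tsv`` (marker_id, transcript_id, beta_median,
    beta_lo, beta_hi, called) and ``run.json`` with the MCMC settings.
    Returns the table as a DataFrame.
    """
    from .sparse_prior import call_associations

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    draws = np.asarray(fit.beta_draws)
    if draws.shape[0] < 2:
        raise ValidationError("need at least 2 retained posterior draws")
    alpha = (1.0 - credible_level) / 2.0
    med = np.median(draws, axis=0)
    lo = np.quantile(draws, alpha, axis=0)
    hi = np.quantile(draws, 1.0 - alpha, axis=0)
    called = call_associations(draws, threshold_sd=fit.config.call_threshold)
    rows = []
    for j, mid in enumerate(fit.marker_ids):
        for k, tid in enumerate(fit.transcript_ids):
            if full or called[j, k]:
                rows.append((mid, tid, med[j, k], lo[j, k], hi[j, k], bool(called[j, k])))
    table = pd.DataFrame(
        rows,
        columns=["marker_id", "transcript_id", "beta_median", "beta_lo", "beta_hi", "called"],
    )
    table.to_csv(out_dir / "associations.tsv", sep="\t", index=False)
    meta = {
        "model": fit.model,
        "transform": fit.transform,
        "iterations": fit.config.n_iter,
        "burnin": fit.config.burnin,
        "seed": fit.config.seed,
        "credible_level": credible_level,
        "call_threshold": fit.config.call_threshold,
        "n_called": int(called.sum()),
    }
    (out_dir / "run.json").write_text(json.dumps(meta, indent=2))
    return table
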