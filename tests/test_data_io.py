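"""Container invariants, TSV/VCF loading, cohort filters and round-trips."""

import numpy as np
import pytest

from eqtlmap.data import (
    CountMatrix,
    EmptyResultError,
    GenotypeMatrix,
    ValidationError,
    filter_markers,
    filter_transcripts,
    load_counts,
    load_genotypes,
    save_counts,
    save_genotypes,
    write_associations,
)

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\tS4
"""


def _write_vcf(path, records):
    path.write_text(VCF_HEADER + "".join(records))
    return path


class TestGenotypeMatrix:
    def test_maf_from_toy_matrix(self):
        g = GenotypeMatrix(np.array([[0, 1, 2], [1, 1, 0]]), ["a", "b"], ["m1", "m2", "m3"])
        assert g.maf == pytest.approx([0.25, 0.5, 0.5])

    def test_entry_outside_domain_rejected(self):
        with pytest.raises(ValidationError, match="outside"):
            GenotypeMatrix(np.array([[0, 3]]), ["a"], ["m1", "m2"])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            GenotypeMatrix(np.zeros((1, 2), dtype=int), ["a"], ["m", "m"])


class TestTsvRoundTrip:
    def test_genotypes(self, tmp_path):
        g = GenotypeMatrix(np.array([[0, 1, 2], [1, 1, 0]]), ["a", "b"], ["m1", "m2", "m3"])
        save_genotypes(g, tmp_path / "g.tsv")
        g2 = load_genotypes(tmp_path / "g.tsv")
        assert np.array_equal(g.values, g2.values)
        assert g.sample_ids == g2.sample_ids and g.marker_ids == g2.marker_ids

    def test_counts(self, tmp_path):
        z = CountMatrix(np.array([[3, 0], [10, 7]]), ["a", "b"], ["t1", "t2"])
        save_counts(z, tmp_path / "z.tsv")
        z2 = load_counts(tmp_path / "z.tsv")
        assert np.array_equal(z.values, z2.values)
        assert z2.transcript_ids == ["t1", "t2"]

    def test_negative_count_rejected(self, tmp_path):
        (tmp_path / "bad.tsv").write_text("sample_id\tt1\ns1\t-1\n")
        with pytest.raises(ValidationError):
            load_counts(tmp_path / "bad.tsv")


class TestVcfLoading:
    def test_basic_dosages(self, tmp_path):
        vcf = _write_vcf(
            tmp_path / "a.vcf",
            ["1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t0/0\n"],
        )
        g = load_genotypes(vcf, format="vcf")
        assert list(g.values[:, 0]) == [0, 1, 2, 0]
        assert g.marker_ids == ["rs1"]

    def test_major_alt_is_folded_to_minor(self, tmp_path):
        # ALT frequency 6/8 = 0.75: dosages must count the REF (minor) allele
        vcf = _write_vcf(
            tmp_path / "b.vcf",
            ["1\t200\trs2\tA\tG\t.\tPASS\t.\tGT\t1/1\t1/1\t1/1\t0/0\n"],
        )
        g = load_genotypes(vcf, format="vcf")
        assert list(g.values[:, 0]) == [0, 0, 0, 2]
        assert g.maf[0] == pytest.approx(0.25)

    def test_multiallelic_skipped_and_missing_imputed(self, tmp_path):
        vcf = _write_vcf(
            tmp_path / "c.vcf",
            [
                "1\t300\trs3\tA\tG,T\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t2/2\n",
                "1\t400\trs4\tA\tG\t.\tPASS\t.\tGT\t./.\t0/1\t0/1\t0/1\n",
            ],
        )
        g = load_genotypes(vcf, format="vcf")
        assert g.marker_ids == ["rs4"]
        assert g.values[0, 0] == 1  # rounded mean of [1,1,1]

    def test_vcf_and_tsv_paths_agree(self, tmp_path):
        vcf = _write_vcf(
            tmp_path / "d.vcf",
            ["1\t500\trs5\tC\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t1/0\n"],
        )
        gv = load_genotypes(vcf, format="vcf")
        save_genotypes(gv, tmp_path / "d.tsv")
        gt = load_genotypes(tmp_path / "d.tsv")
        assert np.array_equal(gv.values, gt.values)


class TestFilters:
    def test_maf_threshold_is_strict(self):
        # maf vector [0.02, 0.05, 0.051, 0.30] with min_maf=0.05 keeps 2
        vals = np.zeros((500, 4), dtype=int)
        for j, maf in enumerate([0.02, 0.05, 0.051, 0.30]):
            n_alt = int(round(maf * 1000))
            vals[: n_alt // 2, j] = 2
            if n_alt % 2:
                vals[n_alt // 2, j] = 1
        g = GenotypeMatrix(vals, [f"s{i}" for i in range(500)], list("abcd"))
        assert g.maf == pytest.approx([0.02, 0.05, 0.051, 0.30])
        kept = filter_markers(g, 0.05)
        assert kept.marker_ids == ["c", "d"]

    def test_zero_threshold_drops_only_monomorphic(self):
        g = GenotypeMatrix(
            np.array([[0, 1], [0, 1]]), ["s1", "s2"], ["mono", "poly"]
        )
        assert filter_markers(g, 0.0).marker_ids == ["poly"]

    def test_all_markers_removed_raises(self):
        g = GenotypeMatrix(np.zeros((2, 2), dtype=int), ["s1", "s2"], ["a", "b"])
        with pytest.raises(EmptyResultError):
            filter_markers(g, 0.05)

    def test_mean_count_threshold_keeps_boundary(self):
        # column sums 39, 40, 41 at N=4: means 9.75, 10, 10.25
        vals = np.array([[39, 40, 41], [0, 0, 0], [0, 0, 0], [0, 0, 0]])
        z = CountMatrix(vals, [f"s{i}" for i in range(4)], ["t1", "t2", "t3"])
        assert filter_transcripts(z, 10.0).transcript_ids == ["t2", "t3"]

    def test_zero_threshold_is_identity(self):
        z = CountMatrix(np.array([[0, 5], [1, 2]]), ["s1", "s2"], ["t1", "t2"])
        assert filter_transcripts(z, 0.0).transcript_ids == ["t1", "t2"]

    def test_filters_idempotent(self, rng):
        g = GenotypeMatrix(
            rng.integers(0, 3, size=(50, 10)), [f"s{i}" for i in range(50)],
            [f"m{j}" for j in range(10)],
        )
        once = filter_markers(g, 0.1)
        twice = filter_markers(once, 0.1)
        assert once.marker_ids == twice.marker_ids
        z = CountMatrix(
            rng.poisson(12, size=(20, 8)), [f"s{i}" for i in range(20)],
            [f"t{j}" for j in range(8)],
        )
        assert (
            filter_transcripts(filter_transcripts(z, 10), 10).transcript_ids
            == filter_transcripts(z, 10).transcript_ids
        )


class TestWriteAssociations:
    def _toy_fit(self, draws):
        from eqtlmap.models import McmcConfig, ModelFit

        return ModelFit(
            model="normal",
            beta_draws=draws,
            mu_draws=np.zeros((draws.shape[0], draws.shape[2])),
            marker_ids=[f"m{j}" for j in range(draws.shape[1])],
            transcript_ids=[f"t{k}" for k in range(draws.shape[2])],
            x_center=np.zeros(draws.shape[1]),
            config=McmcConfig(n_iter=2 * draws.shape[0], burnin=draws.shape[0], seed=0),
        )

    def test_zero_draws_yield_no_calls_but_files(self, tmp_path):
        fit = self._toy_fit(np.zeros((100, 2, 2)))
        table = write_associations(fit, tmp_path, full=True)
        assert len(table) == 4 and not table["called"].any()
        assert (tmp_path / "associations.tsv").exists()
        assert (tmp_path / "run.json").exists()

    def test_credible_interval_percentiles(self, tmp_path, rng):
        draws = rng.standard_normal((500, 1, 1)) + 3.0
        fit = self._toy_fit(draws)
        table = write_associations(fit, tmp_path, credible_level=0.95)
        assert table.loc[0, "beta_lo"] == pytest.approx(
            np.quantile(draws[:, 0, 0], 0.025)
        )
        assert table.loc[0, "beta_hi"] == pytest.approx(
            np.quantile(draws[:, 0, 0], 0.975)
        )
        assert table.loc[0, "beta_lo"] <= table.loc[0, "beta_median"] <= table.loc[0, "beta_hi"]
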