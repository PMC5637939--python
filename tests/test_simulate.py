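"""Simulator statistical checks: Hardy-Weinberg genotypes, Exponential effect
magnitudes, NB/Poisson count moments, noise mechanics, and determinism."""

import json

import numpy as np
import pytest

from eqtlmap.simulate import (
    SimulationConfig,
    SimulationTruth,
    simulate_coefficients,
    simulate_counts,
    simulate_dataset,
    simulate_genotypes,
)


class TestCoefficients:
    def test_zero_budget_zero_matrix(self, rng):
        cfg = SimulationConfig(n_markers=5, n_transcripts=6, n_assoc=0, seed=0)
        truth = simulate_coefficients(cfg, rng)
        assert not truth.nonzero.any()

    def test_truncated_exponential_magnitudes(self, rng):
        cfg = SimulationConfig(
            n_markers=100, n_transcripts=200, n_assoc=10000,
            effect_rate=2.0, seed=0,
        )
        truth = simulate_coefficients(cfg, rng)
        mags = np.abs(truth.b_true[truth.nonzero])
        assert mags.max() <= cfg.effect_max + 1e-12
        # mean of Exp(rate) truncated at t: 1/rate - t/(exp(rate*t)-1)
        t, r = cfg.effect_max, cfg.effect_rate
        expected = 1 / r - t / np.expm1(r * t)
        assert mags.mean() == pytest.approx(expected, rel=0.05)

    def test_sign_balance(self, rng):
        cfg = SimulationConfig(n_markers=100, n_transcripts=200, n_assoc=10000, seed=0)
        truth = simulate_coefficients(cfg, rng)
        frac_pos = (truth.b_true[truth.nonzero] > 0).mean()
        assert abs(frac_pos - 0.5) < 3 * 0.5 / np.sqrt(10000)

    def test_hotspot_and_polygenic_patterns(self, rng):
        cfg = SimulationConfig(
            n_markers=20, n_transcripts=50, n_assoc=5, n_hotspots=1, n_polygenic=1, seed=0
        )
        truth = simulate_coefficients(cfg, rng)
        j = truth.hotspot_markers[0]
        assert truth.nonzero[j].sum() >= int(np.ceil(0.1 * 50))
        t = truth.polygenic_transcripts[0]
        assert truth.nonzero[:, t].sum() >= int(np.ceil(0.1 * 20))

    def test_budget_overflow_rejected(self, rng):
        cfg = SimulationConfig(n_markers=2, n_transcripts=2, n_assoc=10, seed=0)
        with pytest.raises(ValueError):
            simulate_coefficients(cfg, rng)


class TestGenotypes:
    def test_hardy_weinberg_at_half(self, rng):
        cfg = SimulationConfig(n_samples=10000, n_markers=1, maf_range=(0.5, 0.5), seed=0)
        x = simulate_genotypes(cfg, rng)
        freqs = np.bincount(x.values[:, 0], minlength=3) / 10000
        assert freqs == pytest.approx([0.25, 0.5, 0.25], abs=0.02)

    def test_maf_concentration(self, rng):
        cfg = SimulationConfig(n_samples=5000, n_markers=4, maf_range=(0.05, 0.05), seed=0)
        x = simulate_genotypes(cfg, rng)
        se = np.sqrt(0.05 * 0.95 / (2 * 5000))
        assert np.abs(x.maf - 0.05).max() < 4 * se

    def test_genotype_noise_flip_rate(self, rng):
        # resampling changes an entry w.p. 1 - sum_g P(g)^2 under HW
        cfg0 = SimulationConfig(n_samples=3000, n_markers=5, maf_range=(0.3, 0.3), seed=5)
        cfg1 = SimulationConfig(
            n_samples=3000, n_markers=5, maf_range=(0.3, 0.3), noise_geno=1.0, seed=5
        )
        a = simulate_genotypes(cfg0, np.random.default_rng(1)).values
        b = simulate_genotypes(cfg1, np.random.default_rng(1)).values
        p, q = 0.3, 0.7
        probs = np.array([q**2, 2 * p * q, p**2])
        expected = 1 - (probs**2).sum()
        assert (a != b).mean() == pytest.approx(expected, abs=0.03)


class TestCounts:
    def test_poisson_index_of_dispersion(self, rng):
        cfg = SimulationConfig(
            n_samples=2000, n_markers=2, n_transcripts=20, n_assoc=0,
            overdispersed=False, nb_mean_log_sd=0.3, seed=1,
        )
        x, z, truth = simulate_dataset(cfg)
        iod = z.values.var(axis=0) / z.values.mean(axis=0)
        assert np.abs(iod - 1.0).max() < 0.25

    def test_overdispersed_variance_exceeds_mean(self, rng):
        cfg = SimulationConfig(
            n_samples=1000, n_markers=2, n_transcripts=50, n_assoc=0,
            nb_dispersion_shape=2.0, nb_dispersion_rate=2.0, seed=2,
        )
        x, z, truth = simulate_dataset(cfg)
        frac = (z.values.var(axis=0) > z.values.mean(axis=0)).mean()
        assert frac >= 0.95

    def test_effect_fold_change(self, rng):
        # beta = log 2 on one gene: genotype-2 vs genotype-0 mean ratio = 4
        cfg = SimulationConfig(
            n_samples=4000, n_markers=1, n_transcripts=1, n_assoc=0,
            maf_range=(0.5, 0.5), overdispersed=False, nb_mean_log_sd=0.0, seed=3,
        )
        g = np.random.default_rng(3)
        truth = simulate_coefficients(cfg, g)
        truth.b_true[0, 0] = np.log(2.0)
        x = simulate_genotypes(cfg, g)
        z = simulate_counts(x, truth, cfg, g)
        m0 = z.values[x.values[:, 0] == 0, 0].mean()
        m2 = z.values[x.values[:, 0] == 2, 0].mean()
        assert m2 / m0 == pytest.approx(4.0, rel=0.1)

    def test_expression_outliers(self, rng):
        cfg = SimulationConfig(
            n_samples=200, n_transcripts=50, n_markers=2, n_assoc=0,
            noise_expr=0.3, seed=4,
        )
        cfg0 = SimulationConfig(
            n_samples=200, n_transcripts=50, n_markers=2, n_assoc=0, seed=4
        )
        _, z1, _ = simulate_dataset(cfg)
        _, z0, _ = simulate_dataset(cfg0)
        changed = (z1.values != z0.values).mean()
        assert 0.2 < changed < 0.4


class TestDataset:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = SimulationConfig(n_samples=30, n_markers=5, n_transcripts=10, n_assoc=3, seed=9)
        simulate_dataset(cfg, out_dir=tmp_path / "a")
        simulate_dataset(cfg, out_dir=tmp_path / "b")
        for name in ("genotypes.tsv", "counts.tsv", "truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_truth_json_round_trip(self, tmp_path):
        cfg = SimulationConfig(
            n_samples=20, n_markers=6, n_transcripts=8, n_assoc=4,
            n_hotspots=1, seed=10,
        )
        _, _, truth = simulate_dataset(cfg, out_dir=tmp_path)
        back = SimulationTruth.from_json(tmp_path / "truth.json")
        assert np.array_equal(back.b_true, truth.b_true)
        assert back.hotspot_markers == truth.hotspot_markers
        assert back.config == truth.config

    def test_default_cohort_scale_shape(self):
        cfg = SimulationConfig(n_samples=250, n_markers=100, n_transcripts=1000, seed=0)
        assert (cfg.n_samples, cfg.n_markers, cfg.n_transcripts) == (250, 100, 1000)
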