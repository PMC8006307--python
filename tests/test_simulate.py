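"""Generator correctness: seed determinism, meiosis, phenotype model, pools."""

import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal
from scipy import stats as sps

from coldmap import pipeline
from coldmap.phenotype import BulkAssignment
from coldmap.simulate import (
    F2Individual,
    Gamete,
    QtlSpec,
    SimConfig,
    SnpPanel,
    genotype_matrix,
    simulate_f2,
    simulate_founders,
    simulate_phenotypes,
    simulate_pooled_reads,
)


def small_config(**kw):
    defaults = dict(
        chrom_lengths={"chr1": 10_000_000},
        snp_density=100.0,
        n_individuals=100,
        bulk_size=10,
        seed=11,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


def uniform_individuals(n, length, t_count, chrom="chr1"):
    """Individuals whose whole chromosome carries `t_count` tolerant alleles."""
    origins = {2: (0, 0), 1: (0, 1), 0: (1, 1)}[t_count]
    ends = np.array([length], dtype=np.int64)
    return [
        F2Individual(
            {
                chrom: (
                    Gamete(ends.copy(), np.array([origins[0]], dtype=np.int8)),
                    Gamete(ends.copy(), np.array([origins[1]], dtype=np.int8)),
                )
            }
        )
        for _ in range(n)
    ]


class TestConfigValidation:
    def test_zero_length_chromosome_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            SimConfig(chrom_lengths={"chr1": 0})

    def test_qtl_outside_chromosome_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(
                chrom_lengths={"chr1": 100},
                qtl=[QtlSpec("chr1", 1000, 10.0)],
            )

    def test_oversized_bulks_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(chrom_lengths={"chr1": 100}, n_individuals=10, bulk_size=6)

    def test_error_rate_bounds(self):
        with pytest.raises(ValueError):
            SimConfig(chrom_lengths={"chr1": 100}, error_rate=0.2)


class TestFounders:
    def test_zero_density_gives_empty_panel(self):
        panel = simulate_founders(small_config(snp_density=0.0))
        assert len(panel) == 0

    def test_seed_determinism(self):
        cfg = small_config()
        p1 = simulate_founders(cfg)
        p2 = simulate_founders(cfg)
        assert_frame_equal(p1.sites, p2.sites)

    def test_parental_bases_differ(self):
        panel = simulate_founders(small_config())
        assert (panel.sites["t_base"] != panel.sites["s_base"]).all()

    def test_poisson_site_count_mean(self):
        # 200 seeds, density 100/Mb over 10 Mb: mean within 3 SE of 1000
        counts = [
            len(simulate_founders(small_config(seed=s))) for s in range(200)
        ]
        se = np.sqrt(1000 / 200)
        assert abs(np.mean(counts) - 1000) < 3 * se


class TestF2:
    def test_empty_panel_rejected(self):
        cfg = small_config(snp_density=0.0)
        panel = simulate_founders(cfg)
        with pytest.raises(ValueError):
            simulate_f2(panel, cfg)

    def test_mendelian_segregation(self):
        cfg = small_config(n_individuals=460)
        panel = simulate_founders(cfg)
        inds = simulate_f2(panel, cfg)
        pos = panel.positions("chr1")[:5]
        counts = genotype_matrix(inds, "chr1", pos)
        for j in range(counts.shape[1]):
            obs = [np.sum(counts[:, j] == k) for k in (0, 1, 2)]
            chi2 = sps.chisquare(obs, f_exp=[115, 230, 115]).pvalue
            assert chi2 > 0.001

    def test_no_recombination_gives_constant_genotype(self):
        cfg = small_config(recomb_cm_per_mb=0.0)
        panel = simulate_founders(cfg)
        inds = simulate_f2(panel, cfg)
        pos = panel.positions("chr1")
        counts = genotype_matrix(inds, "chr1", pos)
        assert (counts == counts[:, [0]]).all()

    def test_complete_linkage_of_coincident_sites(self):
        cfg = small_config()
        panel = simulate_founders(cfg)
        inds = simulate_f2(panel, cfg)
        p = int(panel.positions("chr1")[0])
        counts = genotype_matrix(inds, "chr1", np.array([p, p]))
        assert (counts[:, 0] == counts[:, 1]).all()


class TestPhenotypes:
    def test_null_model_all_baseline(self):
        cfg = small_config(noise_sd=0.0, sd_noise_sd=0.0, baseline_sr=40.0)
        panel = simulate_founders(cfg)
        inds = simulate_f2(panel, cfg)
        ph = simulate_phenotypes(inds, cfg)
        assert (ph["SR"] == 40.0).all()

    def test_additive_contrast_matches_model(self):
        # a=15, d=0, no noise: mean(SR|TT) - mean(SR|SS) = 2a = 30
        cfg = small_config(
            noise_sd=0.0,
            sd_noise_sd=0.0,
            n_individuals=300,
            bulk_size=30,
            qtl=[QtlSpec("chr1", 5_000_000, 15.0)],
        )
        panel = simulate_founders(cfg)
        inds = simulate_f2(panel, cfg)
        ph = simulate_phenotypes(inds, cfg)
        g = genotype_matrix(inds, "chr1", np.array([5_000_000]))[:, 0]
        assert ph["SR"][g == 2].mean() - ph["SR"][g == 0].mean() == pytest.approx(30.0)

    def test_sr_sd_strongly_anticorrelated(self):
        cfg = pipeline.default_sim_config(seed=3, additive=15.0)
        exp = pipeline.simulate_experiment(cfg)
        r = np.corrcoef(exp.phenotypes["SR"], exp.phenotypes["SD"])[0, 1]
        assert r <= -0.9

    def test_bounds_respected(self):
        cfg = small_config(noise_sd=50.0)
        panel = simulate_founders(cfg)
        inds = simulate_f2(panel, cfg)
        ph = simulate_phenotypes(inds, cfg)
        assert ph["SR"].between(0, 100).all()
        assert ph["SD"].between(0, 7).all()


class TestPooledReads:
    def test_fixed_bulk_means_all_reads_alt(self):
        cfg = small_config(error_rate=0.0, n_individuals=10, bulk_size=5)
        panel = simulate_founders(cfg)
        inds = uniform_individuals(10, 10_000_000, t_count=2)
        bulks = BulkAssignment(
            tolerant_ids={f"L{i:04d}" for i in range(5)},
            sensitive_ids={f"L{i:04d}" for i in range(5, 10)},
        )
        counts = simulate_pooled_reads(inds, bulks, panel, cfg)
        assert (counts["t_ref"] == 0).all()
        assert (counts["s_ref"] == 0).all()

    def test_het_bulk_index_near_half(self):
        cfg = small_config(
            chrom_lengths={"chr1": 100_000_000},
            error_rate=0.0,
            n_individuals=10,
            bulk_size=5,
            mean_depth=100.0,
        )
        panel = simulate_founders(cfg)  # ~10,000 sites
        inds = uniform_individuals(10, 100_000_000, t_count=1)
        bulks = BulkAssignment(
            tolerant_ids={f"L{i:04d}" for i in range(5)},
            sensitive_ids={f"L{i:04d}" for i in range(5, 10)},
        )
        counts = simulate_pooled_reads(inds, bulks, panel, cfg)
        idx = counts["t_alt"] / (counts["t_ref"] + counts["t_alt"])
        se = np.sqrt(0.25 / 100 / len(counts))
        assert abs(idx.mean() - 0.5) < 3 * se

    def test_zero_depth_flagged_unusable(self):
        cfg = small_config(mean_depth=0.0)
        panel = simulate_founders(cfg)
        inds = simulate_f2(panel, cfg)
        bulks = BulkAssignment(
            tolerant_ids={f"L{i:04d}" for i in range(10)},
            sensitive_ids={f"L{i:04d}" for i in range(10, 20)},
        )
        counts = simulate_pooled_reads(inds, bulks, panel, cfg)
        assert (counts[["t_ref", "t_alt", "s_ref", "s_alt"]] == 0).all().all()
        assert (~counts["usable"]).all()

    def test_empty_bulk_rejected(self):
        cfg = small_config()
        panel = simulate_founders(cfg)
        inds = simulate_f2(panel, cfg)
        with pytest.raises(ValueError):
            simulate_pooled_reads(
                inds, BulkAssignment(set(), set()), panel, cfg
            )


class TestEndToEndProperties:
    def test_pipeline_outputs_seed_deterministic(self):
        cfg1 = small_config(qtl=[QtlSpec("chr1", 5_000_000, 15.0)])
        cfg2 = small_config(qtl=[QtlSpec("chr1", 5_000_000, 15.0)])
        e1 = pipeline.simulate_experiment(cfg1)
        e2 = pipeline.simulate_experiment(cfg2)
        assert_frame_equal(e1.counts, e2.counts)
        assert_frame_equal(e1.phenotypes, e2.phenotypes)
        assert e1.bulks.tolerant_ids == e2.bulks.tolerant_ids

    def test_null_delta_sign_symmetric(self):
        # no QTL: the per-site delta distribution is symmetric about zero.
        # Sites within one experiment share bulk-composition noise, so the
        # sign test is run over many independent replicate experiments with
        # a conservative block-variance adjustment (block = one replicate).
        signs = []
        block = 0
        for seed in range(250):
            cfg = SimConfig(
                chrom_lengths={"chr1": 200_000},
                snp_density=100.0,
                n_individuals=60,
                bulk_size=20,
                mean_depth=50.0,
                seed=seed,
            )
            exp = pipeline.simulate_experiment(cfg)
            c = exp.counts
            delta = c["t_alt"] / (c["t_alt"] + c["t_ref"]) - c["s_alt"] / (
                c["s_alt"] + c["s_ref"]
            )
            delta = delta.dropna()
            delta = delta[delta != 0]
            block = max(block, len(delta))
            signs.extend(np.sign(delta).tolist())
        n = len(signs)
        assert n >= 5000
        pos = int(np.sum(np.array(signs) > 0))
        # conservative z-test: Var(pos) <= n * block / 4 under within-block
        # dependence; 3.3 sigma ~ alpha 0.001 two-sided
        assert abs(pos - n / 2) < 3.3 * np.sqrt(n * block / 4)
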