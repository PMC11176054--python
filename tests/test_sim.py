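"""Simulator behaviour: founder panels, gametes, offspring, read sampling."""

import numpy as np
import pandas as pd
import pytest

from polyhap.core import GenomeLayout, ValidationError
from polyhap.sim import (
    CLONAL,
    MEIOTIC,
    SimulationConfig,
    TruncationSpec,
    f1_offspring,
    make_hybrid,
    rng_from,
    simulate_founders,
    simulate_gamete,
    simulate_offspring,
    simulate_reads,
)
from polyhap.pipelines import simulate_sample, simulate_study


class TestFounderPanel:
    def test_private_site_counts_and_disjointness(self):
        # 4 founders, one 10 Mb chromosome, 100 SNPs/Mb, no sharing:
        # each non-reference founder holds ~1,000 private sites, overlap 0
        layout = GenomeLayout((("chr01", 10_000_000),))
        cfg = SimulationConfig(layout=layout, founder_ids=("A", "B", "C", "D"),
                               snp_density=100.0, reference_private_density=0.0,
                               introgressions={}, seed=1)
        panel = simulate_founders(cfg)
        sets = {}
        for fid in ("B", "C", "D"):
            df = panel.variants[fid].df
            assert 1000 - 4 * 32 < len(df) < 1000 + 4 * 32  # 4 sigma of Poisson(1000)
            sets[fid] = set(zip(df["chrom"], df["pos"]))
        assert not (sets["B"] & sets["C"]) and not (sets["B"] & sets["D"]) \
            and not (sets["C"] & sets["D"])
        assert len(panel.variants["A"]) == 0  # reference carries no alt of its own

    def test_zero_density_gives_empty_valid_panel(self, small_layout):
        cfg = SimulationConfig(layout=small_layout, founder_ids=("A", "B"),
                               snp_density=0.0, reference_private_density=0.0,
                               evidence_fp_per_mb=0.0, introgressions={}, seed=2)
        panel = simulate_founders(cfg)
        assert len(panel.site_table) == 0
        assert all(len(v) == 0 for v in panel.variants.values())

    def test_introgression_density_ratio(self):
        # 10x multiplier inside the 5-58 Mb block of a 60 Mb chromosome:
        # in-block vs out-of-block density ratio ~ 10 within Poisson error
        from polyhap.sim import IntrogressionBlock
        layout = GenomeLayout((("chr09", 60_000_000),))
        cfg = SimulationConfig(
            layout=layout, founder_ids=("A", "B"),
            snp_density=0.0, reference_private_density=50.0,
            introgressions={"A": (IntrogressionBlock("chr09", 5_000_000, 58_000_000, 10.0),)},
            seed=3)
        panel = simulate_founders(cfg)
        pos = panel.variants["B"].df["pos"].to_numpy()
        inside = ((pos > 5_000_000) & (pos <= 58_000_000)).sum()
        outside = len(pos) - inside
        d_in = inside / 53.0
        d_out = outside / 7.0
        assert 8.0 < d_in / d_out < 12.5

    def test_evidence_replicates_thin_the_truth(self, small_panel, small_config):
        for fid in small_panel.founder_ids:
            truth = small_panel.variants[fid]
            for rep in small_panel.evidence[fid]:
                merged = rep.df.merge(truth.df[["chrom", "pos"]], on=["chrom", "pos"])
                # replicates are mostly truth sites plus a few false positives
                if len(truth):
                    assert len(merged) / len(truth) > 0.85
                assert len(rep) >= len(merged)

    def test_sharing_fraction_marks_shared_sites(self, small_layout):
        cfg = SimulationConfig(layout=small_layout, founder_ids=("A", "B", "C", "D"),
                               snp_density=60.0, reference_private_density=0.0,
                               sharing_fraction=0.2, introgressions={}, seed=4)
        panel = simulate_founders(cfg)
        shared = panel.site_table[panel.site_table["origin"] == "shared"]
        assert len(shared) > 0
        carriers = shared[list(panel.founder_ids)].sum(axis=1)
        assert (carriers == 2).all()


class TestHybrid:
    def test_private_sites_heterozygous(self, small_panel):
        hyb = make_hybrid(small_panel, "A", "B")
        g = hyb.genotypes()
        st = small_panel.site_table
        b_private = st["origin"] == "private:B"
        assert (g.loc[b_private.to_numpy(), "genotype_class"] == "het").all()
        # a site private to C is homozygous reference in A x B
        c_private = st["origin"] == "private:C"
        assert (g.loc[c_private.to_numpy(), "genotype_class"] == "hom_ref").all()

    def test_self_cross_rejected(self, small_panel):
        with pytest.raises(ValidationError):
            make_hybrid(small_panel, "A", "A")
        with pytest.raises(ValidationError):
            make_hybrid(small_panel, "A", "Z")


class TestGametes:
    def test_clonal_gamete_equals_parent(self, small_panel, small_config):
        hyb = make_hybrid(small_panel, "A", "B")
        g = simulate_gamete(hyb, CLONAL, small_config, rng=rng_from(0, 1))
        assert all(len(bp) == 0 for bp in g.breakpoints.values())
        for chrom, length in small_panel.layout.chromosomes:
            assert g.chromatids[chrom] == (((0, length, "A"),), ((0, length, "B"),))

    def test_obligate_crossover_floor(self, small_panel, small_config):
        hyb = make_hybrid(small_panel, "C", "D")
        for seed in range(25):
            g = simulate_gamete(hyb, MEIOTIC, small_config, rng=rng_from(seed, 1))
            for chrom in small_panel.layout.names:
                assert len(g.breakpoints[chrom]) >= 1

    def test_mosaic_alternates_at_breakpoints(self, small_panel, small_config):
        hyb = make_hybrid(small_panel, "A", "B")
        g = simulate_gamete(hyb, MEIOTIC, small_config, rng=rng_from(7, 1))
        for chrom, length in small_panel.layout.chromosomes:
            (chromatid,) = g.chromatids[chrom]
            # segments tile the chromosome and alternate source haplotypes
            assert chromatid[0][0] == 0 and chromatid[-1][1] == length
            for (s1, e1, h1), (s2, e2, h2) in zip(chromatid[:-1], chromatid[1:]):
                assert e1 == s2 and h1 != h2

    def test_breakpoint_count_matches_model_mean(self):
        # E[max(1, Poisson(lam))] = lam + exp(-lam) with the obligate floor
        layout = GenomeLayout((("chr01", 10_000_000),))
        cfg = SimulationConfig(layout=layout, founder_ids=("A", "B"),
                               snp_density=1.0, reference_private_density=0.0,
                               crossover_rate=1.0, obligate_co=True,
                               introgressions={}, seed=9)
        panel = simulate_founders(cfg)
        hyb = make_hybrid(panel, "A", "B")
        rng = rng_from(9, 1)
        counts = [len(simulate_gamete(hyb, MEIOTIC, cfg, rng=rng).breakpoints["chr01"])
                  for _ in range(600)]
        expected = 1.0 + np.exp(-1.0)
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) < 3 * se + 1e-9


class TestOffspring:
    def test_clonal_union_copy_arithmetic(self, small_panel, small_config):
        hyb1 = make_hybrid(small_panel, "A", "B")
        hyb2 = make_hybrid(small_panel, "C", "D")
        g1 = simulate_gamete(hyb1, CLONAL, small_config, rng=rng_from(0, 1))
        g2 = simulate_gamete(hyb2, CLONAL, small_config, rng=rng_from(0, 2))
        off = simulate_offspring(g1, g2, sample_id="H4")
        assert off.ploidy == 4
        state = off.local_state(small_panel.site_table[["chrom", "pos"]])
        st = small_panel.site_table
        a_private = (st["origin"] == "private:B").to_numpy()
        assert (state.loc[a_private, "cn"] == 4).all()
        assert (state.loc[a_private, "B"] == 1).all()
        assert (state.loc[a_private, "alt_copies"] == 1).all()

    def test_twelve_chromosome_union_gives_48_copies(self):
        from polyhap.core import default_tomato_layout
        layout = default_tomato_layout()
        cfg = SimulationConfig(layout=layout, founder_ids=("A", "B"),
                               snp_density=1.0, reference_private_density=0.0,
                               evidence_fp_per_mb=0.0, seed=12)
        panel = simulate_founders(cfg)
        hyb = make_hybrid(panel, "A", "B")
        g1 = simulate_gamete(hyb, CLONAL, cfg, rng=rng_from(0, 1))
        g2 = simulate_gamete(hyb, CLONAL, cfg, rng=rng_from(0, 2))
        off = simulate_offspring(g1, g2)
        assert off.n_chromosome_copies() == 48

    def test_forced_truncation_reflected_in_cn(self, small_panel, small_config):
        hyb = make_hybrid(small_panel, "A", "B")
        g1 = simulate_gamete(hyb, CLONAL, small_config, rng=rng_from(1, 1))
        g2 = simulate_gamete(hyb, CLONAL, small_config, rng=rng_from(1, 2))
        tr = TruncationSpec(forced=(("chr01", "A", "right", 2_000_000),))
        off = simulate_offspring(g1, g2, truncation=tr)
        cn = off.cn_segments()
        lost = cn[(cn["chrom"] == "chr01") & (cn["copy_number"] == 3)]
        assert len(lost) == 1
        assert lost.iloc[0]["start"] == 6_000_000 and lost.iloc[0]["end"] == 8_000_000
        ev = off.truth.truncations[0]
        assert ev.haplotype == "A" and ev.start == 6_000_000
        # A-allele copies drop to 1 (one of two A chromatids lost) in the interval
        st = small_panel.site_table
        sites = st[(st["chrom"] == "chr01") & (st["pos"] > 6_000_000)][["chrom", "pos"]]
        if len(sites):
            state = off.local_state(sites)
            assert (state["cn"] == 3).all()

    def test_no_truncation_means_uniform_ploidy(self, small_panel, small_config):
        hyb = make_hybrid(small_panel, "A", "B")
        g1 = simulate_gamete(hyb, CLONAL, small_config, rng=rng_from(2, 1))
        g2 = simulate_gamete(hyb, CLONAL, small_config, rng=rng_from(2, 2))
        off = simulate_offspring(g1, g2, truncation=TruncationSpec(prob=0.0))
        cn = off.cn_segments()
        assert (cn["copy_number"] == 4).all()

    def test_clonal_transmission_heterozygosity_union(self, small_panel, small_config):
        # offspring of two clonal gametes is heterozygous at exactly the
        # union of its two parents' heterozygous sites (truth level)
        hyb1 = make_hybrid(small_panel, "A", "B")
        hyb2 = make_hybrid(small_panel, "C", "D")
        g1 = simulate_gamete(hyb1, CLONAL, small_config, rng=rng_from(3, 1))
        g2 = simulate_gamete(hyb2, CLONAL, small_config, rng=rng_from(3, 2))
        off = simulate_offspring(g1, g2)
        state = off.local_state(small_panel.site_table[["chrom", "pos"]])
        het_off = (state["alt_copies"] > 0) & (state["alt_copies"] < state["cn"])
        het_parents = (hyb1.genotypes()["genotype_class"] == "het") | \
                      (hyb2.genotypes()["genotype_class"] == "het")
        assert het_off.tolist() == het_parents.tolist()


class TestReads:
    def test_balanced_sites_mean_half(self, small_panel, small_config):
        hyb = make_hybrid(small_panel, "A", "B")
        off = f1_offspring(hyb)
        sites = small_panel.variants["B"].df[["chrom", "pos"]]
        counts = simulate_reads(off, sites, mean_depth=30, error_rate=0.0,
                                rng=rng_from(4, 3))
        depth = counts.df["ref_count"] + counts.df["alt_count"]
        af = counts.df["alt_count"][depth > 0] / depth[depth > 0]
        se = af.std(ddof=1) / np.sqrt(len(af))
        assert abs(af.mean() - 0.5) < 3 * se

    def test_depth_scales_with_copy_number(self, small_panel, small_config):
        hyb = make_hybrid(small_panel, "A", "B")
        g1 = simulate_gamete(hyb, CLONAL, small_config, rng=rng_from(5, 1))
        g2 = simulate_gamete(hyb, CLONAL, small_config, rng=rng_from(5, 2))
        tr = TruncationSpec(forced=(("chr01", "A", "right", 4_000_000),))
        off = simulate_offspring(g1, g2, truncation=tr)
        sites = small_panel.site_table[["chrom", "pos"]]
        counts = simulate_reads(off, sites, mean_depth=40, error_rate=0.0,
                                rng=rng_from(5, 3))
        merged = counts.df.merge(off.local_state(sites)[["chrom", "pos", "cn"]],
                                 on=["chrom", "pos"])
        depth = merged["ref_count"] + merged["alt_count"]
        lost = merged["cn"] == 3
        assert lost.sum() > 500
        assert abs(depth[lost].mean() / 40 - 0.75) < 0.02
        assert abs(depth[~lost].mean() / 40 - 1.0) < 0.02

    def test_zero_copy_sites_have_zero_depth(self, small_panel, small_config):
        hyb = make_hybrid(small_panel, "A", "B")
        off = f1_offspring(hyb)
        counts = simulate_reads(off, small_panel.site_table[["chrom", "pos"]],
                                mean_depth=30, error_rate=0.01, rng=rng_from(6, 3))
        assert len(counts) == len(small_panel.site_table)  # zero-depth rows retained

    def test_error_rate_bounds(self, small_panel):
        hyb = make_hybrid(small_panel, "A", "B")
        off = f1_offspring(hyb)
        sites = small_panel.site_table[["chrom", "pos"]]
        with pytest.raises(ValidationError):
            simulate_reads(off, sites, mean_depth=30, error_rate=0.5)
        with pytest.raises(ValidationError):
            simulate_reads(off, sites, mean_depth=0, error_rate=0.01)


class TestDeterminism:
    def test_identical_seed_bit_identical_outputs(self, small_layout):
        cfg = SimulationConfig(layout=small_layout, founder_ids=("A", "B"),
                               snp_density=40.0, reference_private_density=40.0,
                               introgressions={}, seed=21)
        samples = [{"id": "S1", "kind": "clonal_tetraploid", "cross": ("A", "B")},
                   {"id": "S2", "kind": "f2", "cross": ("A", "B")}]
        panel1, sims1 = simulate_study(cfg, samples)
        panel2, sims2 = simulate_study(cfg, samples)
        assert panel1.site_table.equals(panel2.site_table)
        for a, b in zip(sims1, sims2):
            assert a.counts.equals(b.counts)
            assert a.offspring.truth.to_json() == b.offspring.truth.to_json()


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"error_rate": 0.5},
        {"error_rate": -0.1},
        {"founder_ids": ("A", "B", "C")},
        {"founder_ids": ("A", "A")},
        {"snp_density": -1.0},
        {"sharing_fraction": 1.5},
    ])
    def test_invalid_config_rejected(self, small_layout, kwargs):
        base = dict(layout=small_layout, founder_ids=("A", "B"), introgressions={})
        base.update(kwargs)
        with pytest.raises(ValidationError):
            SimulationConfig(**base)
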