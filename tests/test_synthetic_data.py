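"""The synthetic generator: determinism, planted structure, and the
statistical properties downstream recovery tests rely on."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methcompare.io_formats import GenomeSequence
from methcompare.methylome import context_arrays
from methcompare.synthetic_data import (
    SimulationConfig,
    make_diploid,
    make_genome,
    simulate_all,
    simulate_bs_reads,
    simulate_rna_and_expression,
)

SMALL = dict(chrom_lengths=(40_000,), n_genes=10, lines=("X",), coverage=8.0,
             tfbs_per_motif=3)


class TestDeterminism:
    def test_identical_config_gives_identical_outputs(self):
        a = simulate_all(SimulationConfig(seed=9, **SMALL))
        b = simulate_all(SimulationConfig(seed=9, **SMALL))
        assert a.genome.seqs == b.genome.seqs
        assert a.haplotypes[1].seqs == b.haplotypes[1].seqs
        pd.testing.assert_frame_equal(a.truth.snps, b.truth.snps)
        pd.testing.assert_frame_equal(a.reads["X"], b.reads["X"])
        pd.testing.assert_frame_equal(a.expression, b.expression)

    def test_different_seeds_differ(self):
        a = simulate_all(SimulationConfig(seed=9, **SMALL))
        b = simulate_all(SimulationConfig(seed=10, **SMALL))
        assert a.genome.seqs != b.genome.seqs


class TestMakeGenome:
    def test_gene_models_within_bounds(self):
        cfg = SimulationConfig(seed=1, chrom_lengths=(100_000,), n_genes=20,
                               tfbs_per_motif=6)
        genome, ann = make_genome(cfg)
        assert len(ann.genes) == 20
        for _, g in ann.genes.iterrows():
            L = genome.lengths[g["chrom"]]
            assert 0 <= g["start"] < g["end"] <= L
            assert g["start"] + g["block_starts"][-1] + g["block_sizes"][-1] == g["end"]

    def test_every_intron_ends_in_ag_acceptor(self):
        cfg = SimulationConfig(seed=1, chrom_lengths=(100_000,), n_genes=20,
                               tfbs_per_motif=6)
        genome, ann = make_genome(cfg)
        for _, g in ann.genes.iterrows():
            seq = genome.seqs[g["chrom"]]
            bs, sz = g["block_starts"], g["block_sizes"]
            for i in range(g["block_count"] - 1):
                iv_start = g["start"] + bs[i] + sz[i]
                iv_end = g["start"] + bs[i + 1]
                if g["strand"] == "+":
                    assert seq[iv_end - 2 : iv_end] == "AG"
                else:  # acceptor on the minus strand: genomic revcomp
                    assert seq[iv_start : iv_start + 2] == "CT"

    def test_capacity_overflow_raises(self):
        with pytest.raises(ValueError, match="capacity"):
            make_genome(SimulationConfig(seed=1, chrom_lengths=(15_000,), n_genes=30,
                                         tfbs_per_motif=1))


class TestMakeDiploid:
    def test_snp_count_within_poisson_bounds(self):
        cfg = SimulationConfig(seed=2, chrom_lengths=(100_000,), n_genes=10,
                               snp_rate=1e-3, tfbs_per_motif=3)
        genome, ann = make_genome(cfg)
        _, _, snps = make_diploid(genome, cfg, annotations=ann)
        assert abs(len(snps) - 100) <= 4 * np.sqrt(100)

    def test_zero_rate_gives_identical_haplotypes(self):
        cfg = SimulationConfig(seed=2, snp_rate=0.0, **SMALL)
        genome, ann = make_genome(cfg)
        h1, h2, snps = make_diploid(genome, cfg, annotations=ann)
        assert len(snps) == 0
        assert h1.seqs == h2.seqs == genome.seqs

    def test_cg_fraction_snps_are_ambiguous_transitions(self):
        cfg = SimulationConfig(seed=2, chrom_lengths=(100_000,), n_genes=10,
                               snp_rate=1e-3, snp_cg_fraction=0.4, tfbs_per_motif=3)
        genome, ann = make_genome(cfg)
        _, _, snps = make_diploid(genome, cfg, annotations=ann)
        cg = snps[snps["is_cg_ref"]]
        assert len(cg) == round(0.4 * len(snps))
        assert set(zip(cg["ref"], cg["alt"])) <= {("C", "T"), ("G", "A")}
        at = snps[~snps["is_cg_ref"]]
        assert set(zip(at["ref"], at["alt"])) <= {("A", "T"), ("T", "A")}


class TestMakeMethylomes:
    def test_tacag_sites_average_twenty_two_percent(self):
        cfg = SimulationConfig(seed=4, lines=("X",))
        sim = simulate_all(cfg)
        vals = []
        for chrom in sim.genome:
            tac = context_arrays(sim.genome.codes(chrom))["is_tacag"]
            arr = sim.truth.probs["X"][1][chrom]
            vals.append(arr[tac & ~np.isnan(arr)])
        vals = np.concatenate(vals)
        assert len(vals) >= 1000
        assert abs(vals.mean() - 0.22) <= 0.02

    def test_fully_symmetric_dyads_share_probabilities(self):
        cfg = SimulationConfig(seed=4, symmetric_fraction=1.0, line_jitter=0.0,
                               n_dmrs=0, asm_fraction=0.0, alt_exon_fraction=0.0,
                               motifs=(), snp_rate=0.0, **{k: v for k, v in SMALL.items()
                                                           if k != "tfbs_per_motif"})
        sim = simulate_all(cfg)
        arr = sim.truth.probs["X"][1]["chr1"]
        ctx = context_arrays(sim.genome.codes("chr1"))["context3"]
        plus_cg = np.flatnonzero(ctx[0] == 0)
        plus_cg = plus_cg[plus_cg + 1 < arr.shape[1]]
        np.testing.assert_allclose(arr[0, plus_cg], arr[1, plus_cg + 1])

    def test_asm_genes_have_allele_gap(self):
        cfg = SimulationConfig(seed=5, asm_fraction=0.3, **SMALL)
        sim = simulate_all(cfg)
        ctx = {c: context_arrays(sim.haplotypes[0].codes(c))["context3"]
               for c in sim.genome}
        for _, g in sim.truth.asm_genes.iterrows():
            cg = ctx[g["chrom"]][:, g["start"] : g["end"]] == 0
            a1 = sim.truth.probs["X"][1][g["chrom"]][:, g["start"] : g["end"]][cg]
            a2 = sim.truth.probs["X"][2][g["chrom"]][:, g["start"] : g["end"]][cg]
            ok = ~np.isnan(a1) & ~np.isnan(a2)
            assert (np.nanmean(a1[ok]) - np.nanmean(a2[ok])) >= (
                cfg.asm_prob_high - cfg.asm_prob_low
            ) - 1e-9


class TestSimulateReads:
    def _tiny(self, prob):
        # trailing TTT keeps every cytosine context-classifiable
        genome = GenomeSequence({"c1": "ACGACGACGACGACGTTT"})
        arr = np.full((2, 18), np.nan)
        ctx = context_arrays(genome.codes("c1"))
        arr[ctx["is_c"] & (ctx["context3"] >= 0)] = prob
        cfg = SimulationConfig(seed=3, read_length=6, coverage=20.0,
                               error_rate=0.0, non_conversion_rate=0.0)
        rng = np.random.default_rng(0)
        return genome, simulate_bs_reads(
            (genome, genome), {1: {"c1": arr}, 2: {"c1": arr}}, cfg, rng, "X"
        )

    def test_probability_one_keeps_every_cytosine(self):
        genome, reads = self._tiny(1.0)
        for _, r in reads[reads["bs_strand"] == "W"].iterrows():
            ref = genome.seqs["c1"][r["start"] : r["start"] + 6]
            for rb, gb in zip(r["seq"], ref):
                if gb == "C":
                    assert rb == "C"

    def test_probability_zero_converts_every_cytosine(self):
        genome, reads = self._tiny(0.0)
        for _, r in reads[reads["bs_strand"] == "W"].iterrows():
            ref = genome.seqs["c1"][r["start"] : r["start"] + 6]
            for rb, gb in zip(r["seq"], ref):
                if gb == "C":
                    assert rb == "T"
        for _, r in reads[reads["bs_strand"] == "C"].iterrows():
            ref = genome.seqs["c1"][r["start"] : r["start"] + 6]
            for rb, gb in zip(r["seq"], ref):
                if gb == "G":
                    assert rb == "A"

    def test_mean_interior_depth_near_target(self):
        cfg = SimulationConfig(seed=6, chrom_lengths=(100_000,), n_genes=10,
                               coverage=30.0, lines=("X",), tfbs_per_motif=3)
        sim = simulate_all(cfg)
        reads = sim.reads["X"]
        depth = np.zeros(100_000)
        for s in reads["start"]:
            depth[s : s + cfg.read_length] += 1
        interior = depth[cfg.read_length : -cfg.read_length]
        assert abs(interior.mean() - 30.0) / 30.0 < 0.10


class TestRnaAndExpression:
    def _single_snp_genes(self, n):
        genes = pd.DataFrame({
            "chrom": "chr1", "start": np.arange(n) * 1000,
            "end": np.arange(n) * 1000 + 500,
            "name": [f"g{i}" for i in range(n)], "score": 0, "strand": "+",
            "thick_start": np.arange(n) * 1000, "thick_end": np.arange(n) * 1000 + 500,
            "item_rgb": "0", "block_count": 1,
            "block_sizes": [[500]] * n, "block_starts": [[0]] * n,
        })
        snps = pd.DataFrame({
            "chrom": "chr1", "pos": np.arange(n) * 1000 + 250,
            "ref": "A", "alt": "T", "is_cg_ref": False,
        })
        return genes, snps

    def test_full_bias_silences_the_minor_allele(self):
        from methcompare.io_formats import AnnotationSet

        genes, snps = self._single_snp_genes(40)
        cfg = SimulationConfig(seed=7, ase_fraction=1.0, ase_bias=1.0,
                               rna_depth=50, motifs=())
        rna, _, ase_truth = simulate_rna_and_expression(
            AnnotationSet(genes=genes), snps, cfg, np.random.default_rng(1)
        )
        counts = rna.set_index(["pos", "allele"])["count"]
        for _, t in ase_truth.iterrows():
            i = int(t["gene_id"][1:])
            minor_allele = "T" if t["biased_hap"] == 1 else "A"
            assert counts[(i * 1000 + 250, minor_allele)] == 0

    def test_balanced_genes_reject_at_the_exact_binomial_rate(self):
        from methcompare.io_formats import AnnotationSet
        from methcompare._stats import exact_binom_two_sided

        genes, snps = self._single_snp_genes(600)
        cfg = SimulationConfig(seed=8, ase_fraction=0.0, rna_depth=100, motifs=())
        rna, _, _ = simulate_rna_and_expression(
            AnnotationSet(genes=genes), snps, cfg, np.random.default_rng(2)
        )
        counts = rna.set_index(["pos", "allele"])["count"]
        ps = []
        for pos in snps["pos"]:
            k = int(counts[(pos, "A")])
            ps.append(exact_binom_two_sided(max(k, 100 - k), 100, 0.5))
        frac = np.mean(np.array(ps) < 0.05)
        # exact two-sided rejection probability at n=100 is 0.0352
        assert 0.01 < frac < 0.07
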