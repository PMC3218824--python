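"""Conservation binning, contingency tables, flank motifs, splice
profiles, exon classes, and strand symmetry."""

import numpy as np
import pandas as pd
import pytest

from conftest import mk_methylome
from methcompare.conservation import (
    build_flank_pfm,
    categorize_level,
    classify_noncg_sites,
    conservation_contingency,
    exon_class_methylation,
    splice_site_profile,
    splice_vs_gene_body,
    symmetry_analysis,
    tacag_fraction,
)
from methcompare.io_formats import GenomeSequence


class TestCategorize:
    @pytest.mark.parametrize(
        "level,klass,meth,expected",
        [
            (0.50, "CG", 5, "medium"),
            (0.33, "CG", 33, "low"),
            (0.334, "CG", 334, "low"),      # rounds to 33
            (0.335, "CG", 335, "medium"),   # rounds to 34
            (0.67, "CG", 67, "high"),
            (0.0, "nonCG", 0, "none"),
            (0.30, "nonCG", 3, "low"),
            (0.31, "nonCG", 31, "high"),
        ],
    )
    def test_bin_edges(self, level, klass, meth, expected):
        assert categorize_level(level, klass, meth_count=meth) == expected

    def test_every_level_maps_to_exactly_one_bin(self):
        for lev in np.linspace(0, 1, 101):
            assert categorize_level(lev, "CG") in {"low", "medium", "high"}
            assert categorize_level(lev, "nonCG", meth_count=1 if lev else 0) in {
                "none", "low", "high"
            }


class TestConservationContingency:
    def test_self_comparison_is_diagonal(self, default_meths):
        cs = conservation_contingency(default_meths["H1"], default_meths["H1"], "CG")
        off_diag = cs.observed.sum() - np.trace(cs.observed)
        assert off_diag == 0
        assert cs.diagonal_fraction == 1.0

    def test_expected_marginals_match_observed(self, default_meths):
        cs = conservation_contingency(default_meths["H1"], default_meths["HSF1"], "CG")
        np.testing.assert_allclose(cs.expected.sum(axis=0), cs.observed.sum(axis=0))
        np.testing.assert_allclose(cs.expected.sum(axis=1), cs.observed.sum(axis=1))

    def test_shared_methylomes_enrich_the_high_high_cell(self, default_meths):
        cs = conservation_contingency(default_meths["H1"], default_meths["HSF1"], "nonCG")
        assert cs.fold[2, 2] > 1.0  # conserved-high non-CG sites

    def test_no_joint_sites_is_an_error(self):
        a = mk_methylome([("c1", 5, "+", "CG", "CG", 1, 10, 0)])
        b = mk_methylome([("c1", 9, "+", "CG", "CG", 1, 10, 0)])
        with pytest.raises(ValueError, match="jointly"):
            conservation_contingency(a, b, "CG")


class TestFlankPfm:
    def test_planted_tacag_sites_give_tacag_consensus(self):
        g = GenomeSequence({"c1": "TTTACAGTTTCTGTATT"})
        # plus-strand motif C at pos 5; minus-strand motif C at pos 13
        sites = pd.DataFrame({
            "chrom": ["c1", "c1"], "pos": [5, 13], "strand": ["+", "-"],
        })
        pfm = build_flank_pfm(sites, g, k=2)
        assert pfm.consensus() == "TACAG"
        assert tacag_fraction(sites, g) == 1.0

    def test_random_sites_recover_background_composition(self, default_sim):
        rng = np.random.default_rng(3)
        genome = default_sim.genome
        chrom = "chr1"
        pos = rng.integers(10, genome.lengths[chrom] - 10, size=4000)
        sites = pd.DataFrame({"chrom": chrom, "pos": pos, "strand": "+"})
        pfm = build_flank_pfm(sites, genome, k=3)
        codes = genome.codes(chrom)
        comp = np.array([(codes == b).mean() for b in range(4)])
        freqs = pfm.frequencies()
        se = np.sqrt(comp * (1 - comp) / len(sites))
        assert (np.abs(freqs - comp[:, None]) <= 4 * se[:, None] + 0.01).all()

    def test_empty_class_is_an_error(self, default_sim):
        with pytest.raises(ValueError, match="empty"):
            build_flank_pfm(pd.DataFrame(columns=["chrom", "pos", "strand"]),
                            default_sim.genome)

    def test_edge_sites_are_dropped_and_counted(self):
        g = GenomeSequence({"c1": "CCCCCCCCCC"})
        sites = pd.DataFrame({"chrom": ["c1", "c1"], "pos": [1, 6], "strand": ["+", "+"]})
        pfm = build_flank_pfm(sites, g, k=3)
        assert pfm.n_sites == 1 and pfm.n_dropped == 1


class TestClassification:
    def test_classes_partition_joint_sites(self, default_meths):
        cls = classify_noncg_sites(list(default_meths.values()))
        assert set(cls["klass"]) <= {
            "conserved_high", "unconserved_methylated", "unmethylated", "other"
        }
        assert len(cls) > 0


class TestSpliceProfile:
    def test_unmethylated_chg_gives_zero_high_fraction(self, default_sim):
        genes = default_sim.annotations.genes
        genome = default_sim.genome
        # methylome with every covered CHG at level 0
        from methcompare.methylome import context_arrays

        rows = []
        for chrom in genome:
            ctx = context_arrays(genome.codes(chrom))["context3"]
            pos = np.flatnonzero(ctx[0] == 1)[:2000]
            for p in pos:
                rows.append((chrom, p + 1, "+", "CHG", "CA", 0, 10, 0))
        table = mk_methylome(rows)
        prof = splice_site_profile(table, genes, genome, side="3p")
        covered = prof[prof["n_covered"] > 0]
        assert (covered["high_fraction"] == 0).all()

    def test_splice_windows_beat_the_rest_of_the_gene_body(
        self, default_sim, default_meths
    ):
        # TACAG acceptors make splice-site non-CG methylation exceed the
        # gene-body background
        res = splice_vs_gene_body(default_meths["H1"], default_sim.annotations.genes)
        assert res["n_splice"] > 50 and res["n_body"] > 500
        assert res["splice_mean"] > res["body_mean"]

    def test_single_exon_genes_are_an_error(self, default_sim):
        genes = default_sim.annotations.genes.copy()
        genes["block_count"] = 1
        with pytest.raises(ValueError, match="multi-exon"):
            splice_site_profile(
                pd.DataFrame(columns=["chrom", "pos", "strand", "context3",
                                      "dinuc", "meth_count", "total_count", "is_tacag"]),
                genes, default_sim.genome,
            )


class TestExonClasses:
    def test_planted_hypomethylation_lowers_alternative_exons(
        self, default_sim, default_meths
    ):
        res = exon_class_methylation(
            default_meths["H1"], default_sim.annotations.genes,
            default_sim.annotations.alt_exons,
        )
        res = res.set_index(["exon_class", "context_class"])["mean_level"]
        assert res[("alternative", "CG")] < res[("interior", "CG")]
        assert res[("alternative", "nonCG")] < res[("interior", "nonCG")]

    def test_missing_alternative_class_is_nan(self, default_sim, default_meths):
        res = exon_class_methylation(
            default_meths["H1"], default_sim.annotations.genes, None
        )
        res = res.set_index(["exon_class", "context_class"])["mean_level"]
        assert np.isnan(res[("alternative", "CG")])
        assert not np.isnan(res[("interior", "CG")])


class TestSymmetry:
    def test_fully_methylated_dyads_are_fully_symmetric(self):
        g = GenomeSequence({"c1": "ACGT"})
        t = mk_methylome([
            ("c1", 2, "+", "CG", "CG", 10, 10, 0),
            ("c1", 3, "-", "CG", "CG", 10, 10, 0),
        ])
        summ, frac = symmetry_analysis(t, g, "CG")
        assert frac == 1.0

    def test_no_dyads_is_an_error(self):
        g = GenomeSequence({"c1": "ACGT"})
        t = mk_methylome([("c1", 2, "+", "CG", "CG", 10, 10, 0)])
        with pytest.raises(ValueError, match="dyads"):
            symmetry_analysis(t, g, "CG")

    def test_chg_partner_offset_is_two(self):
        # plus CHG at pos 1 of CAG; minus partner C sits under the G at pos 3
        g = GenomeSequence({"c1": "CAGTT"})
        t = mk_methylome([
            ("c1", 1, "+", "CHG", "CA", 5, 10, 0),
            ("c1", 3, "-", "CHG", "CT", 5, 10, 0),
        ])
        summ, frac = symmetry_analysis(t, g, "CHG")
        assert summ.grand_total == 1
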