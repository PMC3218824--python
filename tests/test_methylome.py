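"""Context classification, the non-conversion read filter, methylation
calling, and global per-context summaries."""

import numpy as np
import pandas as pd
import pytest

from conftest import mk_methylome, mk_reads
from methcompare.io_formats import GenomeSequence
from methcompare.methylome import (
    assign_context,
    call_methylation,
    global_levels,
    is_nonconverted,
)
from methcompare.synthetic_data import SimulationConfig, simulate_all


class TestAssignContext:
    @pytest.mark.parametrize(
        "seq,pos,strand,expected",
        [
            ("TTACAGT", 4, "+", ("CHG", "CA", True)),   # the TACAG motif cytosine
            ("AACGA", 3, "+", ("CG", "CG", False)),
            ("TCGA", 3, "-", ("CG", "CG", False)),      # minus-strand C under the plus G
            ("ACAT", 2, "+", ("CHH", "CA", False)),
            ("ACTGA", 2, "+", ("CHG", "CT", False)),  # C,T,G: H then G
            ("ACTTA", 2, "+", ("CHH", "CT", False)),
        ],
    )
    def test_examples(self, seq, pos, strand, expected):
        g = GenomeSequence({"c1": seq})
        assert assign_context(g, "c1", pos, strand) == expected

    def test_chromosome_edge_gives_na(self):
        g = GenomeSequence({"c1": "AAAC"})
        ctx, dinuc, tac = assign_context(g, "c1", 4, "+")
        assert ctx == "NA"

    def test_non_cytosine_position_rejected(self):
        g = GenomeSequence({"c1": "AAAA"})
        with pytest.raises(ValueError):
            assign_context(g, "c1", 2, "+")


class TestNonConversionFilter:
    # "CAT" repeats put plus-strand CHH cytosines at starts 0,3,6,9
    genome = GenomeSequence({"c1": "CATCATCATCATAA"})

    def _read(self, seq):
        return mk_reads([("r", "c1", 0, "+", "W", seq)]).iloc[0]

    def test_three_consecutive_methylated_noncg_discarded(self):
        assert is_nonconverted(self._read("CATCATCATTATAA"), self.genome)

    def test_interrupted_run_kept(self):
        # methylated, methylated, unmethylated (T), methylated: max run 2
        assert not is_nonconverted(self._read("CATCATTATCATAA"), self.genome)

    def test_methylated_cg_runs_do_not_count(self):
        g = GenomeSequence({"c1": "CGCGCGCGCGCG"})
        read = mk_reads([("r", "c1", 0, "+", "W", "CGCGCGCGCGCG")]).iloc[0]
        assert not is_nonconverted(read, g)  # 6 methylated CGs, no non-CG

    def test_batch_filter_matches_single_read_rule(self):
        reads = mk_reads([
            ("bad", "c1", 0, "+", "W", "CATCATCATTATAA"),
            ("ok", "c1", 0, "+", "W", "TATTATCATTATAA"),
        ])
        table = call_methylation(reads, self.genome)
        assert table.attrs["n_nonconverted"] == 1
        # surviving read contributes: CHH site at pos 7 covered once
        site = table[(table["pos"] == 7) & (table["strand"] == "+")]
        assert site["total_count"].iloc[0] == 1


class TestCallMethylation:
    def test_c_to_t_ratio_at_cg(self):
        g = GenomeSequence({"c1": "AACGA"})
        reads = mk_reads([
            ("r1", "c1", 0, "+", "W", "AACGA"),
            ("r2", "c1", 0, "+", "W", "AACGA"),
            ("r3", "c1", 0, "+", "W", "AACGA"),
            ("r4", "c1", 0, "+", "W", "AATGA"),
            ("r5", "c1", 0, "+", "W", "AAGGA"),  # G at the C: neither count
        ])
        t = call_methylation(reads, g)
        site = t[(t["pos"] == 3) & (t["strand"] == "+")].iloc[0]
        assert (site["meth_count"], site["total_count"]) == (3, 4)

    def test_crick_reads_report_minus_strand_cytosines(self):
        g = GenomeSequence({"c1": "TCGAA"})
        reads = mk_reads([
            ("r1", "c1", 0, "-", "C", "TCGAA"),  # G retained: methylated
            ("r2", "c1", 0, "-", "C", "TCAAA"),  # G->A: unmethylated
        ])
        t = call_methylation(reads, g)
        site = t[(t["pos"] == 3) & (t["strand"] == "-")].iloc[0]
        assert (site["meth_count"], site["total_count"], site["context3"]) == (1, 2, "CG")
        # Crick reads say nothing about the plus-strand C
        assert len(t[(t["pos"] == 2) & (t["strand"] == "+")]) == 0

    def test_levels_track_true_probabilities_on_clean_reads(self):
        cfg = SimulationConfig(
            seed=21, chrom_lengths=(40_000,), n_genes=8, lines=("X",),
            coverage=25.0, error_rate=0.0, non_conversion_rate=0.0,
            snp_rate=0.0, tfbs_per_motif=2,
        )
        sim = simulate_all(cfg)
        table = call_methylation(sim.reads["X"], sim.genome)
        arr = sim.truth.probs["X"][1]["chr1"]
        s_idx = (table["strand"] == "-").astype(int).to_numpy()
        p = arr[s_idx, table["pos"].to_numpy() - 1]
        n = table["total_count"].to_numpy()
        lev = table["meth_count"].to_numpy() / n
        se = np.sqrt(p * (1 - p) / n)
        # the 3-SE bound only approximates the discrete tail at useful depth
        deep = n >= 10
        violations = np.abs(lev - p)[deep] > (3 * se + 1e-12)[deep]
        assert violations.mean() < 0.02
        # degenerate probabilities are reproduced exactly on clean reads
        exact = (p == 0.0) | (p == 1.0)
        np.testing.assert_allclose(lev[exact], p[exact])


class TestGlobalLevels:
    def test_coverage_floor_excludes_sites(self):
        t = mk_methylome([
            ("c1", 10, "+", "CG", "CG", 8, 10, 0),   # level 0.8, cov 10
            ("c1", 20, "+", "CG", "CG", 3, 5, 0),    # level 0.6, cov 5
            ("c1", 30, "+", "CG", "CG", 2, 3, 0),    # cov 3: excluded
        ])
        gl = global_levels(t, min_coverage=4)
        assert gl.levels["CG"] == pytest.approx((0.8 + 0.6) / 2)
        assert gl.n_sites["CG"] == 2

    def test_empty_context_reported_missing_not_zero(self):
        t = mk_methylome([("c1", 10, "+", "CG", "CG", 8, 10, 0)])
        gl = global_levels(t)
        assert "CHH" not in gl.levels
        assert np.isnan(gl.as_frame().set_index("label").loc["CHH", "mean_level"])

    def test_context_label_ordering_on_default_simulation(self, default_meths):
        gl = global_levels(default_meths["H1"])
        assert gl.levels["TACAG"] > gl.levels["CAG"] > gl.levels["CHH"]
        assert gl.levels["CG"] > gl.levels["CHG"]

    def test_raising_coverage_floor_never_adds_sites(self, default_meths):
        n4 = global_levels(default_meths["H1"], min_coverage=4).n_sites
        n8 = global_levels(default_meths["H1"], min_coverage=8).n_sites
        assert all(n8[label] <= n4[label] for label in n4)

    def test_pooled_mode_weights_by_coverage(self):
        t = mk_methylome([
            ("c1", 10, "+", "CG", "CG", 10, 10, 0),
            ("c1", 20, "+", "CG", "CG", 0, 40, 0),
        ])
        assert global_levels(t, pooled=False).levels["CG"] == pytest.approx(0.5)
        assert global_levels(t, pooled=True).levels["CG"] == pytest.approx(0.2)
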