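"""Bisulfite-aware heterozygous SNP calling and allele-specific expression.

Bisulfite conversion makes read C/T ambiguous wherever the reference has
a cytosine: an unmethylated C reads as T. Read C and T observations
mapped to a genomic C — on either strand, i.e. C/T at reference C and
(in plus-strand orientation) G/A at reference G — are therefore excluded
from allele evidence. Per-allele counts are the average of the tallies
from reads aligned to the two strands. A position is called heterozygous
when the included read coverage is at least 8, the two main alleles
cover more than 75% of included reads, and their counts differ by at
most 20% of their sum.

Allele-specific expression is tested per gene with an exact two-sided
binomial on the summed RNA major/minor counts of its exonic SNPs
(null: both alleles equally covered), thresholded by Benjamini-Hochberg
at 1% FDR; known imprinted genes serve as positive controls via an
upper-tail hypergeometric enrichment.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from ._stats import bh_threshold, exact_binom_two_sided, hypergeom_upper_tail
from .io_formats import GenomeSequence, exon_intervals, seq_to_codes

__all__ = [
    "call_snps",
    "map_exonic_snps",
    "ase_test",
    "calibrate_threshold",
    "imprinted_enrichment",
]

_A, _C, _G, _T = 0, 1, 2, 3
_BASES = "ACGT"


def _pileup(reads: pd.DataFrame, genome: GenomeSequence, chrom: str) -> np.ndarray:
    """Per-position base tallies, stratified by read alignment strand.

    Returns an int array of shape (2, 4, L): axis 0 is alignment strand
    (0='+', 1='-'), axis 1 the read base.
    """
    L = len(genome.seqs[chrom])
    counts = np.zeros((2, 4, L), dtype=np.int64)
    sub = reads[reads["chrom"] == chrom]
    for strand, s_idx in (("+", 0), ("-", 1)):
        grp = sub[sub["strand"] == strand]
        for rl, grp2 in grp.groupby(grp["seq"].str.len()):
            starts = grp2["start"].to_numpy(dtype=np.int64)
            seq_mat = np.vstack([seq_to_codes(s) for s in grp2["seq"]])
            cols = starts[:, None] + np.arange(rl)[None, :]
            for b in range(4):
                np.add.at(counts[s_idx, b], cols[seq_mat == b], 1)
    return counts


def call_snps(
    reads: pd.DataFrame,
    genome: GenomeSequence,
    min_cov: int = 8,
    main_frac: float = 0.75,
    balance: float = 0.20,
    return_audit: bool = False,
):
    """Call heterozygous SNPs from bisulfite reads.

    Returns a table with columns chrom, pos (1-based), allele1, allele2
    (allele1 the better-covered), count1, count2 (strand-averaged),
    coverage (included reads). With ``return_audit`` a second table of
    near-miss positions with status flags (c_ambiguous_excluded,
    low_coverage, unbalanced, impure) is returned as well.

    C/T observations at reference C positions and G/A observations at
    reference G positions are excluded regardless of read strand, so het
    SNPs whose two alleles are exactly that ambiguous pair cannot be
    called from bisulfite data.
    """
    snp_rows = []
    audit_rows = []
    for chrom in genome:
        codes = genome.codes(chrom)
        counts = _pileup(reads, genome, chrom)
        raw_total = counts.sum(axis=(0, 1))
        # bisulfite ambiguity exclusions, keyed on the reference base
        incl = counts.copy()
        ref_c = codes == _C
        ref_g = codes == _G
        incl[:, _C, ref_c] = 0
        incl[:, _T, ref_c] = 0
        incl[:, _G, ref_g] = 0
        incl[:, _A, ref_g] = 0
        avg = incl.astype(float).mean(axis=0)          # (4, L) strand-averaged
        coverage = incl.sum(axis=(0, 1))               # included reads
        order = np.argsort(avg, axis=0)
        a1 = order[-1]
        a2 = order[-2]
        pos_all = np.arange(codes.size)
        c1 = avg[a1, pos_all]
        c2 = avg[a2, pos_all]
        total_avg = avg.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            pure = np.where(total_avg > 0, (c1 + c2) / total_avg, 0.0) > main_frac
        balanced = np.abs(c1 - c2) <= balance * (c1 + c2)
        biallelic = c2 > 0
        covered = coverage >= min_cov
        het = biallelic & covered & pure & balanced
        for p in np.flatnonzero(het):
            snp_rows.append({
                "chrom": chrom, "pos": int(p) + 1,
                "allele1": _BASES[a1[p]], "allele2": _BASES[a2[p]],
                "count1": float(c1[p]), "count2": float(c2[p]),
                "coverage": int(coverage[p]),
            })
        if return_audit:
            # positions that looked heterozygous in the raw tallies
            raw_avg = counts.astype(float).mean(axis=0)
            raw_sorted = np.sort(raw_avg, axis=0)
            cand = (raw_sorted[-2] >= 2) & ~het
            for p in np.flatnonzero(cand):
                flags = []
                if (ref_c[p] or ref_g[p]) and not biallelic[p]:
                    flags.append("c_ambiguous_excluded")
                if not covered[p]:
                    flags.append("low_coverage")
                if biallelic[p] and not balanced[p]:
                    flags.append("unbalanced")
                if biallelic[p] and not pure[p]:
                    flags.append("impure")
                audit_rows.append({
                    "chrom": chrom, "pos": int(p) + 1,
                    "raw_coverage": int(raw_total[p]),
                    "flags": ",".join(flags) or "filtered",
                })
    snps = pd.DataFrame(
        snp_rows,
        columns=["chrom", "pos", "allele1", "allele2", "count1", "count2", "coverage"],
    )
    if return_audit:
        return snps, pd.DataFrame(
            audit_rows, columns=["chrom", "pos", "raw_coverage", "flags"]
        )
    return snps


def map_exonic_snps(
    snps: pd.DataFrame,
    rna_counts: pd.DataFrame,
    genes: pd.DataFrame,
    min_rna: int = 4,
) -> pd.DataFrame:
    """Attach genes and RNA allele counts to heterozygous SNPs.

    Keeps SNPs falling inside an exon block and covered by at least
    ``min_rna`` RNA reads over the two alleles; the allele with more RNA
    reads is the major allele. SNPs inside overlapping genes are assigned
    to each (flagged via ``n_genes``).
    """
    exons = exon_intervals(genes)
    rna = rna_counts.set_index(["chrom", "pos", "allele"])["count"]
    rows = []
    for _, s in snps.iterrows():
        hit = exons[
            (exons["chrom"] == s["chrom"])
            & (exons["start"] < s["pos"])
            & (s["pos"] <= exons["end"])
        ]
        gene_ids = list(dict.fromkeys(hit["gene_id"]))
        if not gene_ids:
            continue
        c1 = int(rna.get((s["chrom"], s["pos"], s["allele1"]), 0))
        c2 = int(rna.get((s["chrom"], s["pos"], s["allele2"]), 0))
        if c1 + c2 < min_rna:
            continue
        major, minor = max(c1, c2), min(c1, c2)
        major_allele = s["allele1"] if c1 >= c2 else s["allele2"]
        for g in gene_ids:
            rows.append({
                "chrom": s["chrom"], "pos": s["pos"], "gene_id": g,
                "allele1": s["allele1"], "allele2": s["allele2"],
                "rna_major": major, "rna_minor": minor,
                "major_allele": major_allele, "n_genes": len(gene_ids),
            })
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "gene_id", "allele1", "allele2",
                 "rna_major", "rna_minor", "major_allele", "n_genes"],
    )


def ase_test(exonic_snps: pd.DataFrame, q: float = 0.01) -> pd.DataFrame:
    """Per-gene allele-specific expression test.

    Sums each exonic SNP's major and minor RNA counts over the gene and
    applies an exact two-sided binomial with p0 = 0.5; ``significant``
    marks genes passing the Benjamini-Hochberg threshold at FDR ``q``
    (the threshold itself is stored in ``df.attrs['threshold']``).
    """
    if len(exonic_snps) == 0:
        raise ValueError("no exonic SNPs to test")
    agg = (
        exonic_snps.groupby("gene_id")
        .agg(n_snps=("pos", "size"), major_total=("rna_major", "sum"),
             minor_total=("rna_minor", "sum"))
        .reset_index()
    )
    total = agg["major_total"] + agg["minor_total"]
    if (total == 0).any():
        raise ValueError("gene with zero RNA reads")
    agg["p_value"] = [
        exact_binom_two_sided(int(k), int(n), 0.5)
        for k, n in zip(agg["major_total"], total)
    ]
    thr = calibrate_threshold(agg["p_value"], q=q)
    agg["significant"] = (agg["p_value"] <= thr) if thr > 0 else False
    agg.attrs["threshold"] = thr
    return agg


def calibrate_threshold(p_values: Sequence[float], q: float = 0.01) -> float:
    """Largest Benjamini-Hochberg-passing p-value at FDR level ``q`` — the
    computable analog of a fixed genome-wide cutoff."""
    return bh_threshold(p_values, q)


def imprinted_enrichment(
    significant_genes: Iterable[str],
    imprinted_genes: Iterable[str],
    universe: Iterable[str],
) -> dict:
    """Upper-tail hypergeometric enrichment of known imprinted genes among
    the significant set, within the testable universe."""
    universe = set(universe)
    sig = set(significant_genes) & universe
    testable = set(imprinted_genes) & universe
    if not testable:
        raise ValueError("no testable imprinted genes in the universe")
    k = len(sig & testable)
    p = hypergeom_upper_tail(k, len(universe), len(sig), len(testable))
    return {"n_testable": len(testable), "n_significant_imprinted": k,
            "n_significant": len(sig), "n_universe": len(universe), "p_value": p}
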