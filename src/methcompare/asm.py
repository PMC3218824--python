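"""Allele-specific methylation from allele-segregated bisulfite reads.

Reads spanning a heterozygous SNP are split into two parental groups by
the allele they show; a cytosine covered by both groups is tested for
differential methylation with a double exact binomial: the methylation
level estimated from one group parameterizes a two-sided binomial test
of the other group's counts, the test is repeated with the groups
swapped, and the larger p-value is kept (so the call is symmetric in the
group labels). Significance is controlled at 5% FDR by
Benjamini-Hochberg across all testable cytosines.

Read-backed phasing reconstructs the per-allele methylation pattern of
the CG sites linked to a SNP by reads spanning both, which turns
intermediate pooled methylation levels into the underlying
one-allele-methylated / other-allele-unmethylated picture.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_reject, bh_threshold, exact_binom_two_sided
from .io_formats import GenomeSequence, exon_intervals
from .methylome import call_methylation

__all__ = [
    "segregate_reads",
    "asm_test",
    "asm_scan",
    "gene_asm_enrichment",
    "phase_methylation",
    "PhasedPattern",
]


def segregate_reads(reads: pd.DataFrame, snp) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Split reads overlapping a het SNP into two allele groups.

    A read joins the group of the allele it shows at the SNP; reads not
    overlapping the SNP, showing neither allele, or whose observation is
    bisulfite-ambiguous (an allele that is a cytosine on the read's
    bisulfite strand, i.e. C for Watson reads or G for Crick reads, seen
    as its possible conversion product) stay unassigned.
    """
    pos0 = int(snp["pos"]) - 1
    a1, a2 = snp["allele1"], snp["allele2"]
    sub = reads[(reads["chrom"] == snp["chrom"])]
    g1, g2, un = [], [], []
    for idx, r in sub.iterrows():
        off = pos0 - r["start"]
        if not 0 <= off < len(r["seq"]):
            un.append(idx)
            continue
        obs = r["seq"][off]
        if r["bs_strand"] == "W" and ("C" in (a1, a2)) and obs in ("C", "T"):
            un.append(idx)
        elif r["bs_strand"] == "C" and ("G" in (a1, a2)) and obs in ("G", "A"):
            un.append(idx)
        elif obs == a1:
            g1.append(idx)
        elif obs == a2:
            g2.append(idx)
        else:
            un.append(idx)
    return reads.loc[g1], reads.loc[g2], reads.loc[un]


def asm_test(k1: int, n1: int, k2: int, n2: int) -> float:
    """Double exact binomial for one cytosine: the larger of the two
    swapped two-sided tests (each conditioning on the other group's
    observed methylation level, unsmoothed)."""
    if n1 < 1 or n2 < 1:
        raise ValueError("both groups need at least one read")
    p_a = exact_binom_two_sided(k2, n2, k1 / n1)
    p_b = exact_binom_two_sided(k1, n1, k2 / n2)
    return max(p_a, p_b)


def asm_scan(
    reads: pd.DataFrame,
    genome: GenomeSequence,
    snps: pd.DataFrame,
    q: float = 0.05,
    context: str = "CG",
    apply_nonconversion_filter: bool = False,
) -> pd.DataFrame:
    """Test every candidate cytosine for allele-specific methylation.

    Candidates are sites (CG context by default) covered by
    allele-assigned reads from both groups of some SNP. A site linked to
    several SNPs is tested once, against the SNP giving it the deepest
    joint coverage (reads are assigned per SNP, so groups stay
    haplotype-consistent). ``q_flag`` marks Benjamini-Hochberg
    significance at FDR ``q``; the overall significant fraction is in
    ``df.attrs['significant_fraction']``.
    """
    read_len = reads["seq"].str.len()
    best: dict = {}
    for _, snp in snps.iterrows():
        pos0 = int(snp["pos"]) - 1
        near = reads[
            (reads["chrom"] == snp["chrom"])
            & (reads["start"] <= pos0)
            & (reads["start"] + read_len > pos0)
        ]
        if len(near) == 0:
            continue
        g1, g2, _ = segregate_reads(near, snp)
        if len(g1) == 0 or len(g2) == 0:
            continue
        m1 = call_methylation(g1, genome, apply_nonconversion_filter=apply_nonconversion_filter)
        m2 = call_methylation(g2, genome, apply_nonconversion_filter=apply_nonconversion_filter)
        if context is not None:
            m1 = m1[m1["context3"] == context]
            m2 = m2[m2["context3"] == context]
        merged = m1.merge(m2, on=["chrom", "pos", "strand"], suffixes=("_1", "_2"))
        merged = merged[(merged["total_count_1"] >= 1) & (merged["total_count_2"] >= 1)]
        for _, row in merged.iterrows():
            key = (row["chrom"], row["pos"], row["strand"])
            depth = row["total_count_1"] + row["total_count_2"]
            if key not in best or depth > best[key]["depth"]:
                best[key] = {
                    "chrom": row["chrom"], "pos": row["pos"], "strand": row["strand"],
                    "snp_pos": snp["pos"],
                    "k1": int(row["meth_count_1"]), "n1": int(row["total_count_1"]),
                    "k2": int(row["meth_count_2"]), "n2": int(row["total_count_2"]),
                    "depth": depth,
                }
    rows = list(best.values())
    out = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "strand", "snp_pos", "k1", "n1", "k2", "n2", "depth"],
    )
    if len(out):
        out["p_value"] = [
            asm_test(r.k1, r.n1, r.k2, r.n2) for r in out.itertuples()
        ]
        out["q_flag"] = bh_reject(out["p_value"], q)
        out = out.sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)
        out.attrs["significant_fraction"] = float(out["q_flag"].mean())
    else:
        out["p_value"] = []
        out["q_flag"] = []
        out.attrs["significant_fraction"] = np.nan
    return out


def gene_asm_enrichment(
    asm_sites: pd.DataFrame,
    genes: pd.DataFrame,
    q: float = 0.05,
    min_tested: int = 3,
) -> pd.DataFrame:
    """Genes enriched in differentially methylated cytosines.

    Per gene with at least ``min_tested`` tested sites in its body, an
    upper-tail binomial of the number significant given the genome-wide
    significant rate, Benjamini-Hochberg flagged at FDR ``q``.
    """
    if len(asm_sites) == 0:
        raise ValueError("no tested cytosines")
    rate = float(asm_sites["q_flag"].mean())
    rows = []
    for _, g in genes.iterrows():
        sel = asm_sites[
            (asm_sites["chrom"] == g["chrom"])
            & (asm_sites["pos"] > g["start"])
            & (asm_sites["pos"] <= g["end"])
        ]
        n = len(sel)
        if n < min_tested:
            continue
        k = int(sel["q_flag"].sum())
        p = float(stats.binom.sf(k - 1, n, rate)) if rate > 0 else (1.0 if k == 0 else 0.0)
        rows.append({"gene_id": g["name"], "n_tested": n, "n_significant": k, "p_value": p})
    out = pd.DataFrame(rows, columns=["gene_id", "n_tested", "n_significant", "p_value"])
    if len(out):
        out["enriched"] = bh_reject(out["p_value"], q)
    else:
        out["enriched"] = []
    out.attrs["global_rate"] = rate
    return out


def intersect_enriched(enriched_by_line: dict[str, Sequence[str]]) -> dict:
    """Genes enriched in at least one line and in multiple lines."""
    sets = {line: set(g) for line, g in enriched_by_line.items()}
    any_line = set().union(*sets.values()) if sets else set()
    multi = {g for g in any_line if sum(g in s for s in sets.values()) >= 2}
    return {"any_line": sorted(any_line), "multiple_lines": sorted(multi)}


@dataclass
class PhasedPattern:
    """Per-allele methylation-state vectors over the CG sites linked to an
    anchor SNP by spanning reads."""

    snp_pos: int
    sites: list[tuple[str, int, str]]          # (chrom, pos, strand), genomic order
    allele1_fraction: np.ndarray               # methylated fraction per site (NaN = no read)
    allele2_fraction: np.ndarray
    allele1_depth: np.ndarray
    allele2_depth: np.ndarray


def phase_methylation(
    reads: pd.DataFrame,
    genome: GenomeSequence,
    snp,
    cg_sites: Optional[pd.DataFrame] = None,
) -> PhasedPattern:
    """Reconstruct the two parental methylation patterns around a SNP.

    Only cytosines sharing at least one read with the SNP contribute;
    per allele the methylated fraction among that allele's reads is
    reported in genomic order. With no spanning read the pattern is
    empty (not an error). ``cg_sites`` optionally restricts the sites
    (columns chrom/pos/strand).
    """
    pos0 = int(snp["pos"]) - 1
    read_len = reads["seq"].str.len()
    near = reads[
        (reads["chrom"] == snp["chrom"])
        & (reads["start"] <= pos0)
        & (reads["start"] + read_len > pos0)
    ]
    g1, g2, _ = segregate_reads(near, snp)
    tables = []
    for grp in (g1, g2):
        if len(grp) == 0:
            tables.append(pd.DataFrame(columns=["chrom", "pos", "strand", "meth_count", "total_count", "context3"]))
            continue
        m = call_methylation(grp, genome, apply_nonconversion_filter=False)
        tables.append(m[m["context3"] == "CG"])
    keys: set = set()
    for t in tables:
        keys |= set(zip(t["chrom"], t["pos"], t["strand"])) if len(t) else set()
    if cg_sites is not None:
        keys &= set(zip(cg_sites["chrom"], cg_sites["pos"], cg_sites["strand"]))
    sites = sorted(keys, key=lambda k: (k[0], k[1], k[2]))
    frac, depth = [], []
    for t in tables:
        idx = {(c, p, s): (m, n) for c, p, s, m, n in zip(
            t["chrom"], t["pos"], t["strand"], t["meth_count"], t["total_count"]
        )} if len(t) else {}
        f = np.full(len(sites), np.nan)
        d = np.zeros(len(sites), dtype=int)
        for i, k in enumerate(sites):
            if k in idx and idx[k][1] > 0:
                f[i] = idx[k][0] / idx[k][1]
                d[i] = idx[k][1]
        frac.append(f)
        depth.append(d)
    return PhasedPattern(
        snp_pos=int(snp["pos"]), sites=sites,
        allele1_fraction=frac[0], allele2_fraction=frac[1],
        allele1_depth=depth[0], allele2_depth=depth[1],
    )
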