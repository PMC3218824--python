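"""From aligned bisulfite reads to a per-cytosine methylome table.

A bisulfite read reports on the cytosines of exactly one genomic strand:
a Watson-strand (``W``) fragment reports plus-strand cytosines (methylated
C stays C, unmethylated C reads T), while a Crick-strand (``C``) fragment
reports minus-strand cytosines, which in plus-strand orientation appear as
G (methylated) versus A (unmethylated).

The methylation level of a cytosine is the ratio of reads showing the
methylated base to reads showing either the methylated or the converted
base; other bases (sequencing errors, SNPs) contribute to neither count.

Reads with three or more consecutive methylated non-CG cytosines — in read
order, skipping CG positions — are treated as bisulfite non-conversion
failures and discarded before calling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import (
    COMPLEMENT_CODE,
    GenomeSequence,
    METHYLOME_COLUMNS,
    methylation_level,
    seq_to_codes,
)

__all__ = [
    "assign_context",
    "context_arrays",
    "is_nonconverted",
    "call_methylation",
    "global_levels",
    "GlobalLevels",
    "GLOBAL_LABELS",
]

_A, _C, _G, _T, _N = 0, 1, 2, 3, 4

# Table-style context labels: the 3-letter contexts, the dinucleotide
# classes pooled over non-CG sites, the CAG trinucleotide subclass and the
# TACAG 5-mer subclass (overlapping classes are intentional).
GLOBAL_LABELS = ["CG", "CHG", "CHH", "CA", "CT", "CC", "CAG", "TACAG"]


def context_arrays(codes: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorized context classification for every position of one
    chromosome, on both strands.

    Returns arrays of shape (2, L) indexed by strand (0 = '+', 1 = '-'):

    * ``is_c``     — position is a cytosine on that strand (N never is)
    * ``context3`` — 0=CG, 1=CHG, 2=CHH, -1 = not a C or too close to the
      chromosome edge to classify (site excluded)
    * ``dinuc``    — code of the base immediately downstream (on-strand)
    * ``is_tacag`` — the strand-oriented 5-mer at offsets -2..+2 is TACAG
    """
    L = codes.size
    ctx = np.full((2, L), -1, dtype=np.int8)
    dinuc = np.full((2, L), -1, dtype=np.int8)
    tacag = np.zeros((2, L), dtype=bool)
    is_c = np.zeros((2, L), dtype=bool)

    # plus strand: C at i, downstream i+1, i+2
    is_c[0] = codes == _C
    if L >= 3:
        c = is_c[0][:-2]
        n1 = codes[1:-1]
        n2 = codes[2:]
        val = np.where(
            n1 == _G, 0, np.where((n2 == _G) & (n1 != _N), 1,
                                  np.where((n1 != _N) & (n2 != _N), 2, -1))
        )
        ctx[0, : L - 2][c] = val[c]
        dinuc[0, : L - 2][c] = n1[c]
    if L >= 5:
        w = (
            (codes[:-4] == _T)
            & (codes[1:-3] == _A)
            & (codes[2:-2] == _C)
            & (codes[3:-1] == _A)
            & (codes[4:] == _G)
        )
        tacag[0, 2 : L - 2] = w

    # minus strand: C at i means plus-strand G; downstream on minus strand
    # is i-1, i-2 read as complements
    is_c[1] = codes == _G
    if L >= 3:
        c = is_c[1][2:]
        n1 = COMPLEMENT_CODE[codes[1:-1]]
        n2 = COMPLEMENT_CODE[codes[:-2]]
        val = np.where(
            n1 == _G, 0, np.where((n2 == _G) & (n1 != _N), 1,
                                  np.where((n1 != _N) & (n2 != _N), 2, -1))
        )
        ctx[1, 2:][c] = val[c]
        dinuc[1, 2:][c] = n1[c]
    if L >= 5:
        # revcomp(TACAG) = CTGTA on the plus strand, C of the motif at i
        w = (
            (codes[:-4] == _C)
            & (codes[1:-3] == _T)
            & (codes[2:-2] == _G)
            & (codes[3:-1] == _T)
            & (codes[4:] == _A)
        )
        tacag[1, 2 : L - 2] = w

    return {"is_c": is_c, "context3": ctx, "dinuc": dinuc, "is_tacag": tacag}


_CTX_NAMES = {0: "CG", 1: "CHG", 2: "CHH", -1: "NA"}
_DINUC_NAMES = {0: "CA", 1: "CC", 2: "CG", 3: "CT"}


def assign_context(genome: GenomeSequence, chrom: str, pos: int, strand: str):
    """Classify the cytosine at 1-based ``pos`` on ``strand``.

    Returns ``(context3, dinuc, is_tacag)`` where context3 is CG/CHG/CHH
    (or ``"NA"`` when the chromosome edge leaves fewer than two downstream
    bases), dinuc is the CN dinucleotide, and is_tacag marks the TACAG
    5-mer read 5'->3' on the named strand.
    """
    codes = genome.codes(chrom)
    i = pos - 1
    s = 0 if strand == "+" else 1
    arrs = context_arrays(codes)
    if not arrs["is_c"][s, i]:
        base = "C" if s == 0 else "G"
        raise ValueError(f"{chrom}:{pos}({strand}) is not a genomic {base}/cytosine")
    ctx = _CTX_NAMES[int(arrs["context3"][s, i])]
    d = int(arrs["dinuc"][s, i])
    dinuc = "C" + "ACGT"[d] if 0 <= d <= 3 else "NA"
    return ctx, dinuc, bool(arrs["is_tacag"][s, i])


# ---------------------------------------------------------------------------
# Non-conversion filter
# ---------------------------------------------------------------------------

def _read_meth_calls(start: int, seq_codes: np.ndarray, bs_strand: str,
                     codes: np.ndarray, ctx: np.ndarray):
    """Positions (read-relative) of bs-strand non-CG cytosines and their
    methylated-call status for one read."""
    L = seq_codes.size
    ref = codes[start : start + L]
    s = 0 if bs_strand == "W" else 1
    meth_base, conv_base = (_C, _T) if s == 0 else (_G, _A)
    is_site = ref == (_C if s == 0 else _G)
    site_ctx = ctx[s, start : start + L]
    noncg = is_site & (site_ctx > 0)  # CHG or CHH (edge/N contexts are -1)
    meth = noncg & (seq_codes == meth_base)
    return noncg, meth


def is_nonconverted(read, genome: GenomeSequence, max_run: int = 2) -> bool:
    """True iff the read shows more than ``max_run`` consecutive methylated
    non-CG cytosines (consecutive among the read's non-CG cytosine
    positions, CG sites skipped) — the signature of a fully unconverted
    molecule.
    """
    codes = genome.codes(read.chrom)
    ctx = context_arrays(codes)["context3"]
    seq_codes = seq_to_codes(read.seq)
    noncg, meth = _read_meth_calls(int(read.start), seq_codes, read.bs_strand, codes, ctx)
    states = meth[noncg]
    run = best = 0
    for m in states:
        run = run + 1 if m else 0
        best = max(best, run)
    return best > max_run


def _nonconverted_rows(starts, seq_mat, s_idx, codes, ctx, max_run=2):
    """Vectorized non-conversion flags for a batch of same-length,
    same-bs-strand reads on one chromosome."""
    n, L = seq_mat.shape
    if n == 0:
        return np.zeros(0, dtype=bool)
    cols = starts[:, None] + np.arange(L)[None, :]
    ref = codes[cols]
    site_ctx = ctx[s_idx][cols]
    meth_base = _C if s_idx == 0 else _G
    cand = (ref == (_C if s_idx == 0 else _G)) & (site_ctx > 0)
    meth = cand & (seq_mat == meth_base)

    rows, cc = np.nonzero(cand)
    if rows.size == 0:
        return np.zeros(n, dtype=bool)
    m = meth[rows, cc].astype(np.int64)
    # run lengths with resets at unmethylated candidates and row boundaries
    idx = np.arange(m.size)
    new_row = np.empty(m.size, dtype=bool)
    new_row[0] = True
    new_row[1:] = rows[1:] != rows[:-1]
    # start index of the run containing i: advanced past unmethylated
    # candidates and pinned at row starts
    start_of_run = np.maximum.accumulate(np.where(m == 0, idx + 1, np.where(new_row, idx, 0)))
    run = np.where(m == 1, idx - start_of_run + 1, 0)
    flag = np.zeros(n, dtype=bool)
    over = run > max_run
    if over.any():
        flag[np.unique(rows[over])] = True
    return flag


# ---------------------------------------------------------------------------
# Methylation calling
# ---------------------------------------------------------------------------

def call_methylation(
    reads: pd.DataFrame,
    genome: GenomeSequence,
    apply_nonconversion_filter: bool = True,
    max_run: int = 2,
) -> pd.DataFrame:
    """Pile up bisulfite reads into a per-cytosine methylome table.

    For every genomic cytosine on each strand, ``meth_count`` counts reads
    of the matching bisulfite strand showing the methylated base and
    ``total_count`` those showing the methylated or the converted base.
    Contexts are attached from the genome; edge sites (context NA) and
    N positions are excluded. Returns a methylome table plus the number of
    reads discarded by the non-conversion filter in ``df.attrs['n_nonconverted']``.
    """
    out_frames = []
    n_discarded = 0
    for chrom, grp in reads.groupby("chrom", sort=True):
        codes = genome.codes(chrom)
        arrs = context_arrays(codes)
        ctx = arrs["context3"]
        L = codes.size
        meth = np.zeros((2, L), dtype=np.int64)
        total = np.zeros((2, L), dtype=np.int64)
        for bs, sub in grp.groupby("bs_strand"):
            s_idx = 0 if bs == "W" else 1
            for rl, sub2 in sub.groupby(sub["seq"].str.len()):
                starts = sub2["start"].to_numpy(dtype=np.int64)
                seq_mat = np.vstack([seq_to_codes(s) for s in sub2["seq"]])
                if apply_nonconversion_filter:
                    bad = _nonconverted_rows(starts, seq_mat, s_idx, codes, ctx, max_run)
                    n_discarded += int(bad.sum())
                    starts = starts[~bad]
                    seq_mat = seq_mat[~bad]
                if starts.size == 0:
                    continue
                cols = starts[:, None] + np.arange(rl)[None, :]
                ref = codes[cols]
                is_site = ref == (_C if s_idx == 0 else _G)
                meth_base, conv_base = (_C, _T) if s_idx == 0 else (_G, _A)
                m = is_site & (seq_mat == meth_base)
                u = is_site & (seq_mat == conv_base)
                np.add.at(meth[s_idx], cols[m], 1)
                np.add.at(total[s_idx], cols[m | u], 1)
        for s_idx, strand in ((0, "+"), (1, "-")):
            covered = (total[s_idx] > 0) & (ctx[s_idx] >= 0)
            pos = np.flatnonzero(covered)
            if pos.size == 0:
                continue
            d = arrs["dinuc"][s_idx][pos]
            out_frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": pos + 1,
                        "strand": strand,
                        "context3": np.array(["CG", "CHG", "CHH"])[ctx[s_idx][pos]],
                        "dinuc": np.array(["CA", "CC", "CG", "CT"])[d],
                        "meth_count": meth[s_idx][pos],
                        "total_count": total[s_idx][pos],
                        "is_tacag": arrs["is_tacag"][s_idx][pos],
                    }
                )
            )
    if out_frames:
        df = pd.concat(out_frames, ignore_index=True)
        df = df.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)
    else:
        df = pd.DataFrame(columns=METHYLOME_COLUMNS)
    df.attrs["n_nonconverted"] = n_discarded
    return df


# ---------------------------------------------------------------------------
# Global per-context summaries
# ---------------------------------------------------------------------------

@dataclass
class GlobalLevels:
    """Mean methylation per context label (fractions), with site counts."""

    levels: dict[str, float]
    n_sites: dict[str, int]
    min_coverage: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": GLOBAL_LABELS,
                "mean_level": [self.levels.get(l, np.nan) for l in GLOBAL_LABELS],
                "n_sites": [self.n_sites.get(l, 0) for l in GLOBAL_LABELS],
            }
        )


def global_levels(methylome: pd.DataFrame, min_coverage: int = 4, pooled: bool = False) -> GlobalLevels:
    """Per-context mean methylation over sites covered by at least
    ``min_coverage`` reads.

    The default is the unweighted mean of per-site levels; ``pooled=True``
    instead divides summed methylated counts by summed totals. Labels with
    no qualifying site are reported as missing (absent), not zero.
    """
    if len(methylome) == 0:
        raise ValueError("empty methylome")
    df = methylome[methylome["total_count"] >= min_coverage]
    level = methylation_level(df)
    noncg = df["context3"].isin(["CHG", "CHH"])
    masks = {
        "CG": df["context3"] == "CG",
        "CHG": df["context3"] == "CHG",
        "CHH": df["context3"] == "CHH",
        "CA": noncg & (df["dinuc"] == "CA"),
        "CT": noncg & (df["dinuc"] == "CT"),
        "CC": noncg & (df["dinuc"] == "CC"),
        "CAG": (df["context3"] == "CHG") & (df["dinuc"] == "CA"),
        "TACAG": df["is_tacag"].astype(bool),
    }
    levels: dict[str, float] = {}
    n_sites: dict[str, int] = {}
    for label, mask in masks.items():
        n = int(mask.sum())
        n_sites[label] = n
        if n == 0:
            continue
        if pooled:
            levels[label] = float(df.loc[mask, "meth_count"].sum() / df.loc[mask, "total_count"].sum())
        else:
            levels[label] = float(level[mask].mean())
    return GlobalLevels(levels=levels, n_sites=n_sites, min_coverage=min_coverage)
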