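"""Cross-line conservation of per-cytosine methylation, flanking-sequence
motif matrices, splice-site CHG profiles, and strand-symmetry analysis.

Methylation levels are discretized into three groups — for CG sites low
(0-33%), medium (34-66%) and high (67-100%) of the rounded percent; for
non-CG sites none (no methylated read), low (0-30%] and high (>30%) —
and a site is conserved when it falls in the same group in both lines.
Observed co-occurrence counts are compared against an independence null
(outer product of the marginals), reported as fold enrichments.

Strand symmetry treats the two cytosines of a CG dyad (or the CHG site
and its minus-strand partner) as the two factors of a 2x2 contingency
table under the same independence null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import COMPLEMENT_CODE, GenomeSequence, exon_intervals, methylation_level
from .methylome import context_arrays

__all__ = [
    "CG_BINS",
    "NONCG_BINS",
    "ContingencySummary",
    "PositionFrequencyMatrix",
    "categorize_level",
    "categorize_series",
    "conservation_contingency",
    "classify_noncg_sites",
    "build_flank_pfm",
    "tacag_fraction",
    "splice_site_profile",
    "exon_class_methylation",
    "splice_vs_gene_body",
    "symmetry_analysis",
]

CG_BINS = ["low", "medium", "high"]
NONCG_BINS = ["none", "low", "high"]


@dataclass
class ContingencySummary:
    """Observed/expected/fold cells of a conservation (3x3) or symmetry
    (2x2) table. Expected assumes independence of the two factors."""

    row_labels: list[str]
    col_labels: list[str]
    observed: np.ndarray
    grand_total: int
    expected: np.ndarray = field(init=False)
    fold: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        obs = np.asarray(self.observed, dtype=float)
        row = obs.sum(axis=1, keepdims=True)
        col = obs.sum(axis=0, keepdims=True)
        self.expected = row * col / self.grand_total
        with np.errstate(invalid="ignore", divide="ignore"):
            self.fold = np.where(self.expected > 0, obs / self.expected, np.nan)

    @property
    def diagonal_fraction(self) -> float:
        return float(np.trace(self.observed) / self.grand_total)


@dataclass
class PositionFrequencyMatrix:
    """Base counts at relative offsets around a set of cytosine sites,
    strand-oriented (minus-strand sites reverse-complemented)."""

    offsets: np.ndarray          # -k .. +k
    counts: np.ndarray           # shape (4, 2k+1), rows A,C,G,T
    n_sites: int
    n_dropped: int               # sites too close to a chromosome edge

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.counts.argmax(axis=0))

    def frequencies(self) -> np.ndarray:
        tot = self.counts.sum(axis=0, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.counts / tot, np.nan)


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------

def categorize_level(level: float, context_class: str, meth_count: Optional[int] = None) -> str:
    """Assign one methylation level to its conservation bin.

    CG uses the rounded percent with integer edges (low <=33, medium
    34-66, high >=67); non-CG distinguishes no methylated read at all
    (``none``), low (level <= 0.30) and high (level > 0.30).
    """
    if not 0.0 <= level <= 1.0:
        raise ValueError(f"level {level} outside [0, 1]")
    if context_class == "CG":
        pct = int(np.floor(100.0 * level + 0.5))
        if pct <= 33:
            return "low"
        if pct <= 66:
            return "medium"
        return "high"
    if context_class == "nonCG":
        none = (meth_count == 0) if meth_count is not None else (level == 0.0)
        if none:
            return "none"
        return "high" if level > 0.30 else "low"
    raise ValueError(f"unknown context class {context_class!r}")


def categorize_series(level: pd.Series, meth_count: pd.Series, context_class: str) -> pd.Series:
    """Vectorized :func:`categorize_level`."""
    lev = level.to_numpy(dtype=float)
    if context_class == "CG":
        pct = np.floor(100.0 * lev + 0.5)
        out = np.where(pct <= 33, "low", np.where(pct <= 66, "medium", "high"))
    else:
        none = meth_count.to_numpy() == 0
        out = np.where(none, "none", np.where(lev > 0.30, "high", "low"))
    return pd.Series(out, index=level.index)


def _class_filter(methylome: pd.DataFrame, context_class: str) -> pd.DataFrame:
    if context_class == "CG":
        return methylome[methylome["context3"] == "CG"]
    if context_class == "nonCG":
        return methylome[methylome["context3"].isin(["CHG", "CHH"])]
    raise ValueError(f"unknown context class {context_class!r}")


# ---------------------------------------------------------------------------
# Pairwise conservation
# ---------------------------------------------------------------------------

_KEY = ["chrom", "pos", "strand"]


def conservation_contingency(
    methylome_a: pd.DataFrame,
    methylome_b: pd.DataFrame,
    context_class: str = "CG",
    min_coverage: int = 4,
) -> ContingencySummary:
    """3x3 contingency of conservation bins between two cell lines, over
    sites covered by at least ``min_coverage`` reads in both.

    ``summary.diagonal_fraction`` is the conserved fraction."""
    a = _class_filter(methylome_a, context_class)
    b = _class_filter(methylome_b, context_class)
    a = a[a["total_count"] >= min_coverage]
    b = b[b["total_count"] >= min_coverage]
    merged = a.merge(b, on=_KEY, suffixes=("_a", "_b"))
    if len(merged) == 0:
        raise ValueError("no jointly covered sites")
    labels = CG_BINS if context_class == "CG" else NONCG_BINS
    bin_a = categorize_series(
        merged["meth_count_a"] / merged["total_count_a"], merged["meth_count_a"], context_class
    )
    bin_b = categorize_series(
        merged["meth_count_b"] / merged["total_count_b"], merged["meth_count_b"], context_class
    )
    obs = np.zeros((3, 3), dtype=np.int64)
    for i, la in enumerate(labels):
        for j, lb in enumerate(labels):
            obs[i, j] = int(((bin_a == la) & (bin_b == lb)).sum())
    return ContingencySummary(labels, labels, obs, int(obs.sum()))


def classify_noncg_sites(
    methylomes: Sequence[pd.DataFrame],
    min_coverage: int = 4,
) -> pd.DataFrame:
    """Classify non-CG cytosines jointly covered in all lines into
    ``conserved_high`` (high in every line), ``unconserved_methylated``
    (high in exactly one line, none in all others) and ``unmethylated``
    (none everywhere). Other combinations get class ``other``."""
    frames = []
    for i, m in enumerate(methylomes):
        sub = _class_filter(m, "nonCG")
        sub = sub[sub["total_count"] >= min_coverage]
        bins = categorize_series(
            sub["meth_count"] / sub["total_count"], sub["meth_count"], "nonCG"
        )
        frames.append(sub[_KEY].assign(**{f"bin{i}": bins.to_numpy()}))
    merged = frames[0]
    for f in frames[1:]:
        merged = merged.merge(f, on=_KEY)
    bin_cols = [c for c in merged.columns if c.startswith("bin")]
    bins = merged[bin_cols].to_numpy()
    n_high = (bins == "high").sum(axis=1)
    n_none = (bins == "none").sum(axis=1)
    k = len(bin_cols)
    klass = np.full(len(merged), "other", dtype=object)
    klass[n_high == k] = "conserved_high"
    klass[(n_high == 1) & (n_none == k - 1)] = "unconserved_methylated"
    klass[n_none == k] = "unmethylated"
    out = merged[_KEY].copy()
    out["klass"] = klass
    return out


# ---------------------------------------------------------------------------
# Flanking-sequence motifs
# ---------------------------------------------------------------------------

def build_flank_pfm(sites: pd.DataFrame, genome: GenomeSequence, k: int = 5) -> PositionFrequencyMatrix:
    """Position frequency matrix of the +-k flank around cytosine sites
    (columns chrom/pos/strand), with the site C at offset 0 and
    minus-strand sites reverse-complemented. Sites within k of a
    chromosome edge are dropped (and counted)."""
    if len(sites) == 0:
        raise ValueError("empty site set")
    width = 2 * k + 1
    counts = np.zeros((4, width), dtype=np.int64)
    dropped = 0
    used = 0
    for chrom, grp in sites.groupby("chrom"):
        codes = genome.codes(chrom)
        L = codes.size
        pos0 = grp["pos"].to_numpy(dtype=np.int64) - 1
        ok = (pos0 >= k) & (pos0 + k < L)
        dropped += int((~ok).sum())
        pos0 = pos0[ok]
        strands = grp["strand"].to_numpy()[ok]
        for s, flip in (("+", False), ("-", True)):
            p = pos0[strands == s]
            if p.size == 0:
                continue
            win = codes[p[:, None] + np.arange(-k, k + 1)[None, :]]
            if flip:
                win = COMPLEMENT_CODE[win[:, ::-1]]
            for b in range(4):
                counts[b] += (win == b).sum(axis=0)
            used += p.size
    return PositionFrequencyMatrix(
        offsets=np.arange(-k, k + 1), counts=counts, n_sites=used, n_dropped=dropped
    )


def tacag_fraction(sites: pd.DataFrame, genome: GenomeSequence) -> float:
    """Fraction of the sites whose strand-oriented -2..+2 5-mer is TACAG."""
    if len(sites) == 0:
        raise ValueError("empty site set")
    hits = 0
    for chrom, grp in sites.groupby("chrom"):
        tac = context_arrays(genome.codes(chrom))["is_tacag"]
        s_idx = (grp["strand"] == "-").astype(int).to_numpy()
        hits += int(tac[s_idx, grp["pos"].to_numpy() - 1].sum())
    return hits / len(sites)


# ---------------------------------------------------------------------------
# Splice sites and exon classes
# ---------------------------------------------------------------------------

def _site_lookup(methylome: pd.DataFrame):
    idx = pd.MultiIndex.from_frame(methylome[_KEY])
    lev = methylation_level(methylome)
    return (
        pd.Series(lev.to_numpy(), index=idx),
        pd.Series(methylome["total_count"].to_numpy(), index=idx),
    )


def _acceptor_positions(genes: pd.DataFrame):
    """(chrom, strand, boundary) per 3' splice site; boundary is the
    0-based genomic position of the first exonic base."""
    out = []
    for _, g in genes.iterrows():
        if g["block_count"] < 2:
            continue
        bs, sz = g["block_starts"], g["block_sizes"]
        if g["strand"] == "+":
            for i in range(1, g["block_count"]):
                out.append((g["chrom"], "+", g["start"] + bs[i]))
        else:
            for i in range(g["block_count"] - 1):
                out.append((g["chrom"], "-", g["start"] + bs[i] + sz[i] - 1))
    return out


def _donor_positions(genes: pd.DataFrame):
    """(chrom, strand, boundary); boundary is the 0-based genomic position
    of the last exonic base before the 5' splice site."""
    out = []
    for _, g in genes.iterrows():
        if g["block_count"] < 2:
            continue
        bs, sz = g["block_starts"], g["block_sizes"]
        if g["strand"] == "+":
            for i in range(g["block_count"] - 1):
                out.append((g["chrom"], "+", g["start"] + bs[i] + sz[i] - 1))
        else:
            for i in range(1, g["block_count"]):
                out.append((g["chrom"], "-", g["start"] + bs[i]))
    return out


def splice_site_profile(
    methylome: pd.DataFrame,
    genes: pd.DataFrame,
    genome: GenomeSequence,
    side: str = "3p",
    window: tuple[int, int] = (-20, 5),
    high_threshold: float = 0.30,
    min_coverage: int = 4,
) -> pd.DataFrame:
    """Per-offset CHG counts and highly-methylated CHG fraction around
    splice sites, on the coding strand.

    For the 3' (acceptor) side offset 0 is the first exonic base and
    offset -1 the last intronic base (the acceptor G), so the canonical
    ``CAG`` acceptor places a CHG cytosine at offset -3. For the 5'
    (donor) side offset 0 is the last exonic base and positive offsets
    run into the intron.
    """
    multi = genes[genes["block_count"] >= 2]
    if len(multi) == 0:
        raise ValueError("no multi-exon genes")
    bounds = _acceptor_positions(multi) if side == "3p" else _donor_positions(multi)
    lev, cov = _site_lookup(methylome)
    ctx_cache = {c: context_arrays(genome.codes(c))["context3"] for c in genome}
    offsets = range(window[0], window[1] + 1)
    rows = []
    for o in offsets:
        n_chg = n_cov = n_high = 0
        for chrom, strand, boundary in bounds:
            if side == "3p":
                p0 = boundary + o if strand == "+" else boundary - o
            else:
                p0 = boundary + o if strand == "+" else boundary - o
            ctx = ctx_cache[chrom]
            L = ctx.shape[1]
            if not 0 <= p0 < L:
                continue
            s_idx = 0 if strand == "+" else 1
            if ctx[s_idx, p0] != 1:  # CHG on the coding strand
                continue
            n_chg += 1
            key = (chrom, p0 + 1, strand)
            if key in lev.index and cov[key] >= min_coverage:
                n_cov += 1
                if lev[key] > high_threshold:
                    n_high += 1
        rows.append({
            "offset": o, "n_chg": n_chg, "n_covered": n_cov,
            "high_fraction": n_high / n_cov if n_cov else np.nan,
        })
    return pd.DataFrame(rows)


def _sites_in_intervals(methylome: pd.DataFrame, intervals: pd.DataFrame) -> np.ndarray:
    """Boolean mask of methylome rows whose cytosine lies in any interval
    (0-based half-open)."""
    mask = np.zeros(len(methylome), dtype=bool)
    pos0 = methylome["pos"].to_numpy() - 1
    for chrom, grp in intervals.groupby("chrom"):
        cm = (methylome["chrom"] == chrom).to_numpy()
        if not cm.any():
            continue
        p = pos0[cm]
        hit = np.zeros(p.size, dtype=bool)
        for _, iv in grp.iterrows():
            hit |= (p >= iv["start"]) & (p < iv["end"])
        mask[np.flatnonzero(cm)[hit]] = True
    return mask


def exon_class_methylation(
    methylome: pd.DataFrame,
    genes: pd.DataFrame,
    alt_exons: Optional[pd.DataFrame],
    min_coverage: int = 4,
) -> pd.DataFrame:
    """Mean CG and non-CG methylation in alternative (cassette) versus
    interior exons (internal blocks not flagged alternative). Missing
    classes yield NaN."""
    df = methylome[methylome["total_count"] >= min_coverage].reset_index(drop=True)
    lev = methylation_level(df)
    exons = exon_intervals(genes)
    interior = exons[(exons["exon_index"] > 0) & (exons["exon_index"] < exons["n_exons"] - 1)]
    if alt_exons is not None and len(alt_exons):
        alt_mask = _sites_in_intervals(df, alt_exons)
        keys = set(zip(alt_exons["chrom"], alt_exons["start"], alt_exons["end"]))
        interior = interior[
            ~interior.apply(lambda r: (r["chrom"], r["start"], r["end"]) in keys, axis=1)
        ]
    else:
        alt_mask = np.zeros(len(df), dtype=bool)
    interior_mask = _sites_in_intervals(df, interior)
    is_cg = (df["context3"] == "CG").to_numpy()
    rows = []
    for klass, mask in (("alternative", alt_mask), ("interior", interior_mask)):
        for ctx_name, cmask in (("CG", is_cg), ("nonCG", ~is_cg)):
            sel = mask & cmask
            rows.append({
                "exon_class": klass, "context_class": ctx_name,
                "mean_level": float(lev[sel].mean()) if sel.any() else np.nan,
                "n_sites": int(sel.sum()),
            })
    return pd.DataFrame(rows)


def splice_vs_gene_body(
    methylome: pd.DataFrame,
    genes: pd.DataFrame,
    min_coverage: int = 4,
    window: tuple[int, int] = (-20, 5),
) -> dict:
    """Mean non-CG methylation within splice-site windows versus the rest
    of the gene body."""
    multi = genes[genes["block_count"] >= 2]
    if len(multi) == 0:
        raise ValueError("no multi-exon genes")
    half = max(abs(window[0]), abs(window[1]))
    splice_iv = []
    for chrom, strand, b in _acceptor_positions(multi) + _donor_positions(multi):
        splice_iv.append({"chrom": chrom, "start": max(0, b - half), "end": b + half + 1})
    splice_iv = pd.DataFrame(splice_iv)
    body_iv = genes[["chrom", "start", "end"]]
    df = methylome[
        (methylome["total_count"] >= min_coverage)
        & methylome["context3"].isin(["CHG", "CHH"])
    ].reset_index(drop=True)
    lev = methylation_level(df)
    in_splice = _sites_in_intervals(df, splice_iv)
    in_body = _sites_in_intervals(df, body_iv)
    sp = in_splice & in_body
    rest = in_body & ~in_splice
    return {
        "splice_mean": float(lev[sp].mean()) if sp.any() else np.nan,
        "body_mean": float(lev[rest].mean()) if rest.any() else np.nan,
        "n_splice": int(sp.sum()),
        "n_body": int(rest.sum()),
    }


# ---------------------------------------------------------------------------
# Strand symmetry
# ---------------------------------------------------------------------------

def symmetry_analysis(
    methylome: pd.DataFrame,
    genome: GenomeSequence,
    context_class: str = "CG",
    binarize_threshold: float = 0.0,
    stratum: str = "all",
    min_coverage: int = 4,
):
    """2x2 contingency of methylation status on the two strands of CG
    dyads (or CHG sites and their minus-strand partners).

    For ``stratum='all'`` the per-strand factor is level >
    ``binarize_threshold``; for ``'low'``/``'high'`` it is membership in
    that stratum (level < 0.30 / level > 0.30). Returns
    ``(ContingencySummary, symmetric_fraction)`` where the fraction counts
    dyads with both strands in the methylated (or in-stratum) state.
    """
    ctx_name = {"CG": "CG", "CHG": "CHG"}[context_class]
    gap = 1 if context_class == "CG" else 2  # minus partner at pos + gap
    df = methylome[
        (methylome["context3"] == ctx_name) & (methylome["total_count"] >= min_coverage)
    ]
    plus = df[df["strand"] == "+"]
    minus = df[df["strand"] == "-"].copy()
    minus["pos"] = minus["pos"] - gap
    merged = plus.merge(minus, on=["chrom", "pos"], suffixes=("_p", "_m"))
    if len(merged) == 0:
        raise ValueError("no qualifying dyads")
    lev_p = merged["meth_count_p"] / merged["total_count_p"]
    lev_m = merged["meth_count_m"] / merged["total_count_m"]
    if stratum == "all":
        f_p = lev_p > binarize_threshold
        f_m = lev_m > binarize_threshold
    elif stratum == "low":
        f_p = lev_p < 0.30
        f_m = lev_m < 0.30
    elif stratum == "high":
        f_p = lev_p > 0.30
        f_m = lev_m > 0.30
    else:
        raise ValueError(f"unknown stratum {stratum!r}")
    obs = np.array([
        [int((~f_p & ~f_m).sum()), int((~f_p & f_m).sum())],
        [int((f_p & ~f_m).sum()), int((f_p & f_m).sum())],
    ])
    summary = ContingencySummary(["unmeth", "meth"], ["unmeth", "meth"], obs, int(obs.sum()))
    symmetric_fraction = float(obs[1, 1] / obs.sum())
    return summary, symmetric_fraction
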