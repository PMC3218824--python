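"""Window-based differential methylation between cell-line pairs.

The genome is tiled into fixed windows (1 kb by default); a window's
methylation is the unweighted mean of its qualifying per-site levels.
For a pair of lines the ratio of the more-methylated to less-methylated
window mean (with a small pseudocount) is standardized over all jointly
scored windows, and windows whose standard score exceeds 2 are called
differentially methylated. Conserved DMRs are windows flagged in all
three pairwise comparisons; their false-discovery rate is estimated by
re-running the calls on permuted window-mean vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenomeSequence, methylation_level

__all__ = [
    "window_methylation",
    "call_dmrs",
    "conserved_dmrs",
    "permutation_fdr",
    "feature_enrichment",
    "island_expression_correlation",
]


def window_methylation(
    methylome: pd.DataFrame,
    window_size: int = 1000,
    min_sites: int = 5,
    min_coverage: int = 4,
    context: str = "CG",
    chrom_lengths: Optional[dict[str, int]] = None,
) -> pd.DataFrame:
    """Tile chromosomes into fixed windows and average the qualifying
    per-site levels of the requested context within each.

    Windows with fewer than ``min_sites`` covered sites get NaN. When
    ``chrom_lengths`` is given the full tiling is emitted (so that
    fractions of the genome are well defined); otherwise only windows
    containing at least one site appear.
    """
    if context == "CG":
        df = methylome[methylome["context3"] == "CG"]
    elif context == "CHG":
        df = methylome[methylome["context3"] == "CHG"]
    else:
        raise ValueError(f"unsupported context {context!r}")
    df = df[df["total_count"] >= min_coverage]
    lev = methylation_level(df)
    win = (df["pos"].to_numpy() - 1) // window_size * window_size
    agg = (
        pd.DataFrame({"chrom": df["chrom"].to_numpy(), "start": win, "level": lev.to_numpy()})
        .groupby(["chrom", "start"])
        .agg(mean_level=("level", "mean"), n_sites=("level", "size"))
        .reset_index()
    )
    agg.loc[agg["n_sites"] < min_sites, "mean_level"] = np.nan
    if chrom_lengths is not None:
        rows = []
        for chrom, L in chrom_lengths.items():
            for s in range(0, L - window_size + 1, window_size):
                rows.append((chrom, s))
        full = pd.DataFrame(rows, columns=["chrom", "start"])
        agg = full.merge(agg, on=["chrom", "start"], how="left")
        agg["n_sites"] = agg["n_sites"].fillna(0).astype(int)
    return agg


def call_dmrs(
    windows_a: pd.DataFrame,
    windows_b: pd.DataFrame,
    z_cut: float = 2.0,
    epsilon: float = 0.01,
) -> pd.DataFrame:
    """Call differentially methylated windows between two lines.

    For each jointly scored window, r = (higher mean + eps)/(lower mean +
    eps) and direction records which line is higher; z standardizes r over
    all such windows and ``is_dmr`` flags z > ``z_cut``.
    """
    m = windows_a.merge(windows_b, on=["chrom", "start"], suffixes=("_a", "_b"))
    m = m.dropna(subset=["mean_level_a", "mean_level_b"]).reset_index(drop=True)
    if len(m) < 30:
        raise ValueError("fewer than 30 jointly scored windows; Z undefined")
    a = m["mean_level_a"].to_numpy()
    b = m["mean_level_b"].to_numpy()
    hi = np.maximum(a, b)
    lo = np.minimum(a, b)
    r = (hi + epsilon) / (lo + epsilon)
    sd = r.std(ddof=0)
    if sd == 0:
        raise ValueError("degenerate ratio distribution")
    z = (r - r.mean()) / sd
    return pd.DataFrame({
        "chrom": m["chrom"], "start": m["start"],
        "mean_a": a, "mean_b": b, "ratio": r,
        "direction": np.where(a >= b, "a", "b"),
        "z": z, "is_dmr": z > z_cut,
    })


def conserved_dmrs(
    dmrs_ab: pd.DataFrame, dmrs_ac: pd.DataFrame, dmrs_bc: pd.DataFrame,
    n_windows_total: Optional[int] = None,
):
    """Windows flagged in all three pairwise comparisons.

    Returns ``(window_frame, fraction)``: the fraction of the genome's
    windows (``n_windows_total`` when given, else the union of scored
    windows) that are conserved DMRs.
    """
    sets = []
    for d in (dmrs_ab, dmrs_ac, dmrs_bc):
        sets.append(set(map(tuple, d.loc[d["is_dmr"], ["chrom", "start"]].to_numpy())))
    common = sets[0] & sets[1] & sets[2]
    if n_windows_total is None:
        union = set()
        for d in (dmrs_ab, dmrs_ac, dmrs_bc):
            union |= set(map(tuple, d[["chrom", "start"]].to_numpy()))
        n_windows_total = len(union)
    frame = pd.DataFrame(sorted(common), columns=["chrom", "start"])
    fraction = len(common) / n_windows_total if n_windows_total else 0.0
    return frame, fraction


def permutation_fdr(
    windows_by_line: dict[str, pd.DataFrame],
    n_perm: int = 300,
    seed: int = 0,
    z_cut: float = 2.0,
    epsilon: float = 0.01,
) -> dict:
    """Permutation estimate of the conserved-DMR false-discovery rate.

    Each permutation independently shuffles each line's vector of
    non-missing window means (the multiset of means is preserved),
    re-calls pairwise DMRs and their three-way overlap, and records the
    conserved fraction; FDR = mean null fraction / observed fraction.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    lines = list(windows_by_line)
    if len(lines) != 3:
        raise ValueError("exactly three cell lines required")
    pairs = [(lines[0], lines[1]), (lines[0], lines[2]), (lines[1], lines[2])]
    n_total = len(windows_by_line[lines[0]])

    def conserved_fraction(tabs):
        calls = [call_dmrs(tabs[a], tabs[b], z_cut=z_cut, epsilon=epsilon) for a, b in pairs]
        _, frac = conserved_dmrs(*calls, n_windows_total=n_total)
        return frac

    observed = conserved_fraction(windows_by_line)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        shuffled = {}
        for line in lines:
            t = windows_by_line[line].copy()
            vals = t["mean_level"].to_numpy().copy()
            ok = ~np.isnan(vals)
            perm = vals[ok]
            rng.shuffle(perm)
            vals[ok] = perm
            # invariant: shuffling permutes, never alters, the means
            assert np.array_equal(
                np.sort(vals[~np.isnan(vals)]),
                np.sort(windows_by_line[line]["mean_level"].dropna().to_numpy()),
            )
            t["mean_level"] = vals
            shuffled[line] = t
        null[i] = conserved_fraction(shuffled)
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=0))
    fdr = null_mean / observed if observed > 0 else np.nan
    return {
        "observed_fraction": observed,
        "null_mean": null_mean,
        "null_sd": null_sd,
        "fdr": fdr,
        "n_perm": n_perm,
    }


def feature_enrichment(
    regions: pd.DataFrame,
    annotations,
    chrom_lengths: dict[str, int],
    shore_width: int = 2000,
) -> pd.DataFrame:
    """Fold enrichment of region base pairs in genomic features.

    fold = (fraction of region bases in feature) / (fraction of genome
    bases in feature); shores are the 2-kb flanks of CpG islands,
    excluding the islands themselves. Features absent from the
    annotation set come back as NaN.
    """
    if len(regions) == 0:
        raise ValueError("empty region set")
    masks = {c: np.zeros(L, dtype=bool) for c, L in chrom_lengths.items()}
    for _, r in regions.iterrows():
        masks[r["chrom"]][r["start"] : r["end"]] = True
    genome_bp = sum(chrom_lengths.values())
    region_bp = sum(int(m.sum()) for m in masks.values())

    def feature_mask(df):
        fm = {c: np.zeros(L, dtype=bool) for c, L in chrom_lengths.items()}
        for _, r in df.iterrows():
            if r["chrom"] in fm:
                fm[r["chrom"]][max(0, r["start"]) : r["end"]] = True
        return fm

    features: dict[str, Optional[pd.DataFrame]] = {}
    genes = annotations.genes
    if genes is not None and len(genes):
        from .io_formats import exon_intervals

        ex = exon_intervals(genes)
        features["exon"] = ex[["chrom", "start", "end"]]
        intr = []
        for _, g in genes.iterrows():
            bs, sz = g["block_starts"], g["block_sizes"]
            for i in range(g["block_count"] - 1):
                intr.append((g["chrom"], g["start"] + bs[i] + sz[i], g["start"] + bs[i + 1]))
        features["intron"] = pd.DataFrame(intr, columns=["chrom", "start", "end"])
    else:
        features["exon"] = features["intron"] = None
    features["promoter"] = annotations.promoters
    features["cpg_island"] = annotations.cpg_islands
    islands = annotations.cpg_islands
    if islands is not None and len(islands):
        sh = islands.copy()
        rows = []
        for _, r in sh.iterrows():
            rows.append((r["chrom"], max(0, r["start"] - shore_width), r["start"]))
            rows.append((r["chrom"], r["end"], min(chrom_lengths[r["chrom"]], r["end"] + shore_width)))
        shores = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        shores = shores[shores["end"] > shores["start"]]
        features["shore"] = shores
    else:
        features["shore"] = None

    island_mask = feature_mask(islands) if islands is not None and len(islands) else None
    rows = []
    for name, df in features.items():
        if df is None or len(df) == 0:
            rows.append({"feature": name, "fold": np.nan, "region_fraction": np.nan,
                         "genome_fraction": np.nan})
            continue
        fm = feature_mask(df)
        if name == "shore" and island_mask is not None:
            for c in fm:
                fm[c] &= ~island_mask[c]
        feat_bp = sum(int(m.sum()) for m in fm.values())
        in_region = sum(int((fm[c] & masks[c]).sum()) for c in fm)
        gf = feat_bp / genome_bp
        rf = in_region / region_bp if region_bp else np.nan
        rows.append({
            "feature": name,
            "fold": rf / gf if gf > 0 else np.nan,
            "region_fraction": rf,
            "genome_fraction": gf,
        })
    return pd.DataFrame(rows)


def island_expression_correlation(delta_meth: pd.Series, delta_expr: pd.Series):
    """Pearson correlation of per-gene CpG-island methylation change
    versus log2 expression change (genes aligned by index)."""
    joined = pd.concat([delta_meth.rename("dm"), delta_expr.rename("de")], axis=1).dropna()
    if len(joined) < 3:
        raise ValueError("fewer than 3 genes with island methylation and expression changes")
    r, p = stats.pearsonr(joined["dm"], joined["de"])
    return float(r), float(p)
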