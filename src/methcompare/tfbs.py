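"""Methylation sensitivity of transcription-factor binding sites.

For a pair of cell lines, the change in CG methylation at each binding
site of a motif is correlated (Pearson) with the log2 change in
expression of the site's assigned gene, and the same correlation is
computed with the methylation of the +-500 bp neighborhood (site
excluded). A motif passes the screen when it has at least ten scored
sites and a site correlation p-value below 0.05; it is called
methylation-sensitive when the site correlation also exceeds the
neighbor correlation in magnitude — evidence that expression tracks the
binding site itself rather than regional methylation drift.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import methylation_level

__all__ = ["site_methylation", "neighbor_methylation", "motif_correlation"]


def _interval_means(
    methylome: pd.DataFrame,
    intervals: pd.DataFrame,
    min_coverage: int,
    context: Optional[str],
    exclude: Optional[pd.DataFrame] = None,
) -> pd.Series:
    df = methylome[methylome["total_count"] >= min_coverage]
    if context is not None:
        df = df[df["context3"] == context]
    lev = methylation_level(df)
    out = np.full(len(intervals), np.nan)
    for chrom, grp in df.groupby("chrom"):
        sel = intervals["chrom"] == chrom
        if not sel.any():
            continue
        pos0 = np.sort(grp["pos"].to_numpy() - 1)
        order = np.argsort(grp["pos"].to_numpy())
        vals = lev.loc[grp.index].to_numpy()[order]
        for i in np.flatnonzero(sel.to_numpy()):
            s, e = intervals.iloc[i]["start"], intervals.iloc[i]["end"]
            lo, hi = np.searchsorted(pos0, [s, e])
            if exclude is not None:
                xs, xe = exclude.iloc[i]["start"], exclude.iloc[i]["end"]
                keep = (pos0[lo:hi] < xs) | (pos0[lo:hi] >= xe)
                v = vals[lo:hi][keep]
            else:
                v = vals[lo:hi]
            if v.size:
                out[i] = v.mean()
    return pd.Series(out, index=intervals.index)


def site_methylation(
    methylome: pd.DataFrame,
    tfbs: pd.DataFrame,
    min_coverage: int = 4,
    context: str = "CG",
) -> pd.Series:
    """Unweighted mean level of covered cytosines inside each TFBS
    interval (NaN when none is covered)."""
    return _interval_means(methylome, tfbs, min_coverage, context)


def neighbor_methylation(
    methylome: pd.DataFrame,
    tfbs: pd.DataFrame,
    span: int = 500,
    min_coverage: int = 4,
    context: str = "CG",
) -> pd.Series:
    """Mean level over +-``span`` bp around each site, excluding the site
    interval itself."""
    widened = tfbs.copy()
    widened["start"] = (tfbs["start"] - span).clip(lower=0)
    widened["end"] = tfbs["end"] + span
    return _interval_means(methylome, widened, min_coverage, context, exclude=tfbs)


def motif_correlation(
    methylome_a: pd.DataFrame,
    methylome_b: pd.DataFrame,
    expression: pd.DataFrame,
    tfbs: pd.DataFrame,
    line_a: str,
    line_b: str,
    min_sites: int = 10,
    p_cut: float = 0.05,
    min_abs_delta: float = 0.1,
    neighbor_span: int = 500,
    min_coverage: int = 4,
    log2_expression: bool = True,
    dedup_genes: bool = False,
) -> pd.DataFrame:
    """Per-motif correlation of methylation change with expression change.

    Per site: dm = site mean in line B minus line A, de = log2(e_B + 1) -
    log2(e_A + 1) for the assigned gene; sites are kept when both means
    are defined and |dm| >= ``min_abs_delta``. Every motif in the TFBS
    table yields exactly one record; records with fewer than two kept
    sites carry NaN correlations. ``dedup_genes`` keeps one site per
    gene (the first in file order).
    """
    sm_a = site_methylation(methylome_a, tfbs, min_coverage)
    sm_b = site_methylation(methylome_b, tfbs, min_coverage)
    nb_a = neighbor_methylation(methylome_a, tfbs, neighbor_span, min_coverage)
    nb_b = neighbor_methylation(methylome_b, tfbs, neighbor_span, min_coverage)

    def expr(line, gene):
        if gene in expression.index and line in expression.columns:
            v = expression.at[gene, line]
            return np.log2(v + 1.0) if log2_expression else v
        return np.nan

    per_site = tfbs.copy()
    per_site["dm"] = sm_b - sm_a
    per_site["dm_neighbor"] = nb_b - nb_a
    per_site["de"] = [
        expr(line_b, g) - expr(line_a, g) for g in per_site["gene"]
    ]
    per_site["motif_id"] = per_site["name"].str.split(":").str[0]
    per_site["tf_name"] = per_site["name"].str.split(":").str[1]

    records = []
    for motif_id, grp in per_site.groupby("motif_id", sort=True):
        if dedup_genes:
            grp = grp.drop_duplicates(subset="gene")
        kept = grp.dropna(subset=["dm", "de"])
        kept = kept[kept["dm"].abs() >= min_abs_delta]
        r_site = p_site = r_nb = p_nb = np.nan
        if len(kept) >= 2 and kept["dm"].nunique() > 1 and kept["de"].nunique() > 1:
            r_site, p_site = stats.pearsonr(kept["dm"], kept["de"])
        nb = kept.dropna(subset=["dm_neighbor"])
        if len(nb) >= 2 and nb["dm_neighbor"].nunique() > 1 and nb["de"].nunique() > 1:
            r_nb, p_nb = stats.pearsonr(nb["dm_neighbor"], nb["de"])
        passes = bool(len(kept) >= min_sites and not np.isnan(p_site) and p_site < p_cut)
        sensitive = bool(passes and not np.isnan(r_nb) and abs(r_site) > abs(r_nb))
        records.append({
            "motif_id": motif_id,
            "tf_name": grp["tf_name"].iloc[0],
            "n_sites": int(len(kept)),
            "r_site": float(r_site) if not np.isnan(r_site) else np.nan,
            "p_site": float(p_site) if not np.isnan(p_site) else np.nan,
            "r_neighbor": float(r_nb) if not np.isnan(r_nb) else np.nan,
            "p_neighbor": float(p_nb) if not np.isnan(p_nb) else np.nan,
            "passes_filters": passes,
            "methylation_sensitive": sensitive,
        })
    return pd.DataFrame(records)
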