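"""Synthetic diploid methylome simulator with planted truth.

The generator emulates the statistical structure of human embryonic stem
cell methylomes so that every downstream stage has a parameter-recovery
test without external data:

* bimodal CG methylation (two-component Beta mixture), mostly-symmetric
  CG dyads, low non-CG methylation with an elevated TACAG motif class
  (mean 22% by default);
* multi-exon gene models whose introns end in canonical ``AG`` acceptors
  preceded by ``C`` (the ``CAG`` acceptor, optionally ``TACAG``), CpG
  islands at a fraction of promoters, and TFBS motifs upstream of genes;
* a diploid genome with heterozygous SNPs, a configurable fraction of
  which sit on reference C/G positions as C/T (G/A) transitions — the
  class that bisulfite conversion makes structurally ambiguous;
* planted differentially methylated 1-kb windows, allele-specifically
  methylated genes, allele-specifically expressed genes, and
  methylation-sensitive TFBS motifs whose target-gene expression tracks
  site methylation.

All randomness flows from one seeded generator, so identical configs give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .io_formats import (
    AnnotationSet,
    GenomeSequence,
    codes_to_seq,
    seq_to_codes,
    write_bed,
    write_bsreads_tsv,
    write_expression_tsv,
    write_fasta,
)
from .methylome import context_arrays

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "SimResult",
    "make_genome",
    "make_diploid",
    "make_methylomes",
    "simulate_bs_reads",
    "simulate_rna_and_expression",
    "simulate_all",
]

_A, _C, _G, _T = 0, 1, 2, 3


@dataclass
class SimulationConfig:
    """Study conditions for one simulated comparison of cell lines.

    Defaults encode the structure the pipeline is designed to detect:
    CG methylation as 0.25*Beta(1,9) + 0.75*Beta(9,1) (bimodal, mostly
    high), non-CG as Beta(0.5,15) (low), TACAG cytosines at mean 0.22,
    77% of CG dyads sharing one probability across strands, and planted
    DMR/ASE/ASM/TFBS effects of realistic magnitude.
    """

    seed: int = 0
    # genome
    chrom_lengths: tuple[int, ...] = (80_000, 60_000)
    gc_content: float = 0.42
    n_genes: int = 40
    gene_exon_range: tuple[int, int] = (3, 5)
    exon_size_range: tuple[int, int] = (80, 200)
    intron_size_range: tuple[int, int] = (150, 400)
    tacag_per_kb: float = 20.0
    tacag_acceptor_frac: float = 0.5
    island_fraction: float = 0.6
    island_halfwidth: int = 200
    alt_exon_fraction: float = 0.25
    # diploid
    snp_rate: float = 1e-3
    snp_cg_fraction: float = 0.25
    # reads
    lines: tuple[str, ...] = ("H1", "HSF1", "H9")
    read_length: int = 75
    coverage: float = 30.0
    non_conversion_rate: float = 0.005
    error_rate: float = 0.002
    # methylation probabilities
    cg_low_weight: float = 0.25
    cg_low_beta: tuple[float, float] = (1.0, 9.0)
    cg_high_beta: tuple[float, float] = (9.0, 1.0)
    noncg_beta: tuple[float, float] = (0.5, 15.0)
    tacag_mean: float = 0.22
    tacag_concentration: float = 10.0
    symmetric_fraction: float = 0.77
    line_jitter: float = 0.02
    line_independent: bool = False
    alt_exon_meth_factor: float = 0.4
    # planted effects
    n_dmrs: int = 12
    dmr_size: int = 1000
    dmr_effect: float = 0.4
    asm_fraction: float = 0.15
    asm_prob_high: float = 0.9
    asm_prob_low: float = 0.1
    # expression / RNA
    ase_fraction: float = 0.2
    ase_bias: float = 0.9
    rna_depth: int = 60
    motifs: tuple[tuple[str, str, float], ...] = (
        ("M001", "REP1", -2.0),
        ("M002", "ACT1", 2.0),
        ("M003", "NULL1", 0.0),
    )
    tfbs_per_motif: int = 12
    tfbs_site_len: int = 10
    expr_base_mean: float = 5.0
    expr_base_sd: float = 1.5
    expr_noise: float = 0.25

    def __post_init__(self) -> None:
        for name in (
            "gc_content", "tacag_acceptor_frac", "island_fraction",
            "alt_exon_fraction", "snp_cg_fraction", "non_conversion_rate",
            "error_rate", "cg_low_weight", "tacag_mean", "symmetric_fraction",
            "asm_fraction", "asm_prob_high", "asm_prob_low", "ase_fraction",
            "ase_bias",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("snp_rate", "coverage", "line_jitter", "dmr_effect",
                     "tacag_per_kb", "expr_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if sum(self.chrom_lengths) < 10_000:
            raise ValueError("genome must be at least 10 kb")


@dataclass
class TruthSet:
    """Planted ground truth, sufficient for every recovery test."""

    snps: pd.DataFrame                 # chrom,pos,ref,alt,is_cg_ref
    ase_genes: pd.DataFrame            # gene_id,biased_hap,bias
    asm_genes: pd.DataFrame            # gene_id,chrom,start,end
    dmrs: pd.DataFrame                 # chrom,start,end,line_up,line_down,effect
    tfbs_states: pd.DataFrame          # line,motif_id,site_index,chrom,start,end,gene,meth_state
    probs: dict                        # line -> allele -> chrom -> (2, L) float array
    motif_effects: pd.DataFrame        # motif_id,tf_name,effect

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.snps.to_csv(outdir / "truth_snps.tsv", sep="\t", index=False)
        self.ase_genes.to_csv(outdir / "truth_ase_genes.tsv", sep="\t", index=False)
        self.asm_genes.to_csv(outdir / "truth_asm_genes.tsv", sep="\t", index=False)
        self.dmrs.to_csv(outdir / "truth_dmrs.tsv", sep="\t", index=False)
        self.tfbs_states.to_csv(outdir / "truth_tfbs_states.tsv", sep="\t", index=False)
        self.motif_effects.to_csv(outdir / "truth_motifs.tsv", sep="\t", index=False)
        rows = []
        for line, alleles in self.probs.items():
            for allele, chroms in alleles.items():
                for chrom, arr in chroms.items():
                    for s_idx, strand in ((0, "+"), (1, "-")):
                        pos = np.flatnonzero(~np.isnan(arr[s_idx]))
                        rows.append(pd.DataFrame({
                            "line": line, "allele": allele, "chrom": chrom,
                            "pos": pos + 1, "strand": strand,
                            "prob": np.round(arr[s_idx][pos], 6),
                        }))
        pd.concat(rows, ignore_index=True).to_csv(
            outdir / "truth_meth_probs.tsv", sep="\t", index=False
        )


@dataclass
class SimResult:
    config: SimulationConfig
    genome: GenomeSequence
    annotations: AnnotationSet
    haplotypes: tuple[GenomeSequence, GenomeSequence]
    truth: TruthSet
    reads: dict[str, pd.DataFrame]
    rna_counts: pd.DataFrame
    expression: pd.DataFrame


# ---------------------------------------------------------------------------
# Genome and annotations
# ---------------------------------------------------------------------------

def _stamp(arr: np.ndarray, start: int, motif: str) -> None:
    m = seq_to_codes(motif)
    arr[start : start + m.size] = m


def make_genome(config: SimulationConfig, rng: Optional[np.random.Generator] = None):
    """Random genome with genes (canonical splice signals), TACAG motif
    occurrences, CpG islands at a fraction of promoters, and TFBS motif
    instances upstream of genes.

    Returns ``(GenomeSequence, AnnotationSet)``.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    gc = config.gc_content
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    chrom_names = [f"chr{i + 1}" for i in range(len(config.chrom_lengths))]
    arrs = {
        name: rng.choice(4, size=L, p=base_p).astype(np.uint8)
        for name, L in zip(chrom_names, config.chrom_lengths)
    }

    # scatter TACAG instances (random strand) before any other feature
    for name, arr in arrs.items():
        n = int(round(config.tacag_per_kb * arr.size / 1000))
        if n == 0:
            continue
        pos = np.sort(rng.choice(arr.size - 5, size=min(n * 2, arr.size // 6), replace=False))
        keep = np.concatenate([[True], np.diff(pos) >= 6])
        pos = pos[keep][:n]
        strands = rng.random(pos.size) < 0.5
        for p, plus in zip(pos, strands):
            _stamp(arr, int(p), "TACAG" if plus else "CTGTA")

    # place genes on a lattice with upstream room for promoters/TFBSs
    upstream = 1600
    gene_rows = []
    chrom_cursor = {name: upstream for name in chrom_names}
    order = list(chrom_names)
    ci = 0
    for gi in range(config.n_genes):
        n_ex = int(rng.integers(config.gene_exon_range[0], config.gene_exon_range[1] + 1))
        ex_sizes = rng.integers(*config.exon_size_range, size=n_ex, endpoint=True)
        in_sizes = rng.integers(*config.intron_size_range, size=n_ex - 1, endpoint=True)
        span = int(ex_sizes.sum() + in_sizes.sum())
        placed = False
        for _ in range(len(order)):
            name = order[ci % len(order)]
            cur = chrom_cursor[name]
            if cur + span + 200 <= arrs[name].size - 5:
                strand = "+" if rng.random() < 0.5 else "-"
                starts = np.concatenate([[0], np.cumsum(ex_sizes[:-1] + in_sizes)])
                gene_rows.append({
                    "chrom": name, "start": cur, "end": cur + span,
                    "name": f"gene{gi:03d}", "score": 0, "strand": strand,
                    "thick_start": cur, "thick_end": cur + span, "item_rgb": "0",
                    "block_count": n_ex,
                    "block_sizes": [int(x) for x in ex_sizes],
                    "block_starts": [int(x) for x in starts],
                })
                chrom_cursor[name] = cur + span + 200 + upstream
                placed = True
                ci += 1
                break
            ci += 1
        if not placed:
            raise ValueError("requested features exceed genome capacity")
    genes = pd.DataFrame(gene_rows)

    # CpG islands at a fraction of promoters: CG-enriched sequence at TSS
    island_rows = []
    promoter_rows = []
    for _, g in genes.iterrows():
        tss = g["start"] if g["strand"] == "+" else g["end"]
        L = arrs[g["chrom"]].size
        promoter_rows.append({
            "chrom": g["chrom"], "start": max(0, tss - 1000),
            "end": min(L, tss + 1000), "name": g["name"], "score": 0,
            "strand": g["strand"],
        })
        if rng.random() < config.island_fraction:
            s = max(0, tss - config.island_halfwidth)
            e = min(L, tss + config.island_halfwidth)
            island_rows.append({"chrom": g["chrom"], "start": s, "end": e})
            arr = arrs[g["chrom"]]
            for p in range(s, e - 1, 4):
                if rng.random() < 0.5:
                    _stamp(arr, p, "CG")
    islands = pd.DataFrame(island_rows, columns=["chrom", "start", "end"])
    promoters = pd.DataFrame(
        promoter_rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )

    # canonical splice signals (stamped after islands so they always win):
    # transcript introns end in AG preceded by C ("CAG" acceptor, a share of
    # them as the full TACAG), and begin with GT
    for _, g in genes.iterrows():
        arr = arrs[g["chrom"]]
        bs, sz = g["block_starts"], g["block_sizes"]
        for i in range(g["block_count"] - 1):
            iv_start = g["start"] + bs[i] + sz[i]
            iv_end = g["start"] + bs[i + 1]
            use_tacag = rng.random() < config.tacag_acceptor_frac
            if g["strand"] == "+":
                _stamp(arr, iv_start, "GT")
                if use_tacag:
                    _stamp(arr, iv_end - 5, "TACAG")
                else:
                    _stamp(arr, iv_end - 3, "CAG")
            else:
                _stamp(arr, iv_end - 2, "AC")
                if use_tacag:
                    _stamp(arr, iv_start, "CTGTA")
                else:
                    _stamp(arr, iv_start, "CTG")

    # alternative (cassette) exons among internal exon blocks
    alt_rows = []
    for _, g in genes.iterrows():
        for i in range(1, g["block_count"] - 1):
            if rng.random() < config.alt_exon_fraction:
                s = g["start"] + g["block_starts"][i]
                alt_rows.append({
                    "chrom": g["chrom"], "start": s, "end": s + g["block_sizes"][i],
                    "name": g["name"], "score": 0, "strand": g["strand"],
                })
    alt_exons = pd.DataFrame(
        alt_rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )

    # TFBS motif instances upstream of genes (one gene per site, genes
    # partitioned among motifs so regulatory effects stay attributable)
    tfbs_rows = []
    if config.motifs:
        need = len(config.motifs) * config.tfbs_per_motif
        if need > len(genes):
            raise ValueError("requested features exceed genome capacity (TFBS genes)")
        gene_pool = list(rng.permutation(genes["name"].to_numpy()))
        gene_ix = genes.set_index("name")
        for motif_id, tf_name, _eff in config.motifs:
            consensus = codes_to_seq(rng.choice(4, size=config.tfbs_site_len).astype(np.uint8))
            half = config.tfbs_site_len // 2
            consensus = consensus[: half - 1] + "CG" + consensus[half + 1:]
            for _ in range(config.tfbs_per_motif):
                gname = gene_pool.pop()
                g = gene_ix.loc[gname]
                offset = int(rng.integers(400, 1100))
                if g["strand"] == "+":
                    s = g["start"] - offset - config.tfbs_site_len
                else:
                    s = g["end"] + offset
                arr = arrs[g["chrom"]]
                s = int(np.clip(s, 0, arr.size - config.tfbs_site_len))
                _stamp(arr, s, consensus)
                tfbs_rows.append({
                    "chrom": g["chrom"], "start": s, "end": s + config.tfbs_site_len,
                    "name": f"{motif_id}:{tf_name}", "score": 0.05, "strand": "+",
                    "gene": gname,
                })
    tfbs = pd.DataFrame(
        tfbs_rows, columns=["chrom", "start", "end", "name", "score", "strand", "gene"]
    )

    genome = GenomeSequence({name: codes_to_seq(arr) for name, arr in arrs.items()})
    ann = AnnotationSet(
        genes=genes, cpg_islands=islands, promoters=promoters,
        alt_exons=alt_exons, tfbs=tfbs,
    )
    return genome, ann


# ---------------------------------------------------------------------------
# Diploid
# ---------------------------------------------------------------------------

def make_diploid(
    genome: GenomeSequence,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    annotations: Optional[AnnotationSet] = None,
):
    """Plant biallelic heterozygous SNPs: haplotype 1 carries the reference
    allele, haplotype 2 the alternate.

    A ``snp_cg_fraction`` share of sites sits on reference C/G positions as
    C>T (G>A) transitions — the class bisulfite conversion cannot
    distinguish from methylation state. The remaining SNPs are A<->T so
    that conversion chemistry leaves their read evidence untouched; SNPs
    are never placed on N or inside TFBS motif instances.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    snp_rows = []
    hap2_seqs = {}
    tfbs = annotations.tfbs if annotations is not None else None
    for chrom, seq in genome.seqs.items():
        codes = genome.codes(chrom).copy()
        blocked = np.zeros(codes.size, dtype=bool)
        if tfbs is not None and len(tfbs):
            for _, t in tfbs[tfbs["chrom"] == chrom].iterrows():
                blocked[t["start"] : t["end"]] = True
        at_pos = np.flatnonzero(((codes == _A) | (codes == _T)) & ~blocked)
        cg_pos = np.flatnonzero(((codes == _C) | (codes == _G)) & ~blocked)
        n_total = rng.binomial(at_pos.size + cg_pos.size, config.snp_rate)
        n_cg = min(int(round(n_total * config.snp_cg_fraction)), cg_pos.size)
        n_at = min(n_total - n_cg, at_pos.size)
        chosen_at = rng.choice(at_pos, size=n_at, replace=False) if n_at else np.empty(0, int)
        chosen_cg = rng.choice(cg_pos, size=n_cg, replace=False) if n_cg else np.empty(0, int)
        hap2 = codes.copy()
        for p in chosen_at:
            alt = _T if codes[p] == _A else _A
            hap2[p] = alt
            snp_rows.append((chrom, int(p) + 1, "ACGTN"[codes[p]], "ACGTN"[alt], False))
        for p in chosen_cg:
            alt = _T if codes[p] == _C else _A
            hap2[p] = alt
            snp_rows.append((chrom, int(p) + 1, "ACGTN"[codes[p]], "ACGTN"[alt], True))
        hap2_seqs[chrom] = codes_to_seq(hap2)
    snps = pd.DataFrame(snp_rows, columns=["chrom", "pos", "ref", "alt", "is_cg_ref"])
    snps = snps.sort_values(["chrom", "pos"]).reset_index(drop=True)
    hap1 = GenomeSequence(dict(genome.seqs))
    hap2 = GenomeSequence(hap2_seqs)
    return hap1, hap2, snps


# ---------------------------------------------------------------------------
# Methylation probability maps
# ---------------------------------------------------------------------------

def _cg_mixture(rng, n, config):
    low = rng.random(n) < config.cg_low_weight
    a = np.where(low, config.cg_low_beta[0], config.cg_high_beta[0])
    b = np.where(low, config.cg_low_beta[1], config.cg_high_beta[1])
    return rng.beta(a, b)


def _draw_base_probs(ctx, rng, config):
    """One (2, L) array of per-cytosine methylation probabilities for a
    single sequence: Beta mixtures by context, CG dyads sharing one value
    across strands for a ``symmetric_fraction`` of dyads."""
    c3 = ctx["context3"]
    tac = ctx["is_tacag"]
    arr = np.full(c3.shape, np.nan, dtype=np.float64)
    noncg = c3 >= 1
    n = int(noncg.sum())
    arr[noncg] = rng.beta(*config.noncg_beta, size=n)
    tmask = tac & (c3 >= 1)
    a = config.tacag_mean * config.tacag_concentration
    b = (1 - config.tacag_mean) * config.tacag_concentration
    arr[tmask] = rng.beta(a, b, size=int(tmask.sum()))
    # CG dyads: plus C at i pairs with minus C at i+1
    plus_cg = np.flatnonzero(c3[0] == 0)
    d1 = _cg_mixture(rng, plus_cg.size, config)
    arr[0, plus_cg] = d1
    partner = plus_cg + 1
    valid = partner < c3.shape[1]
    shared = rng.random(plus_cg.size) < config.symmetric_fraction
    d2 = np.where(shared, d1, _cg_mixture(rng, plus_cg.size, config))
    arr[1, partner[valid]] = d2[valid]
    # edge CG sites without a drawn partner
    rest = (c3 == 0) & np.isnan(arr)
    arr[rest] = _cg_mixture(rng, int(rest.sum()), config)
    return arr


def make_methylomes(
    genome: GenomeSequence,
    haplotypes,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    annotations: Optional[AnnotationSet] = None,
):
    """Per-cell-line, per-allele methylation probability maps with planted
    truth.

    Unless ``line_independent`` is set, all lines share one base map up to
    Gaussian jitter, so non-planted regions are conserved across lines.
    Planted structure (applied in this order): alternative-exon
    hypomethylation, DMR windows (one line shifted up, another down, CG
    sites only), ASM genes (allele 1 high / allele 2 low at gene-body CG
    sites), and per-line binary methylation states at TFBS instances.

    Returns ``(probs, dmr_truth, asm_truth, tfbs_truth)`` where probs maps
    line -> allele -> chrom -> (2, L) array.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    hap1, hap2 = haplotypes
    ann = annotations if annotations is not None else AnnotationSet()
    chroms = list(genome.seqs)

    ctx_ref = {c: context_arrays(genome.codes(c)) for c in chroms}
    ctx_hap = {
        1: {c: context_arrays(hap1.codes(c)) for c in chroms},
        2: {c: context_arrays(hap2.codes(c)) for c in chroms},
    }

    # global planting decisions -------------------------------------------
    genes = ann.genes if ann.genes is not None else pd.DataFrame()
    n_asm = int(round(config.asm_fraction * len(genes))) if len(genes) else 0
    asm_idx = rng.choice(len(genes), size=n_asm, replace=False) if n_asm else []
    asm_truth = (
        genes.iloc[sorted(asm_idx)][["name", "chrom", "start", "end"]]
        .rename(columns={"name": "gene_id"})
        .reset_index(drop=True)
        if n_asm
        else pd.DataFrame(columns=["gene_id", "chrom", "start", "end"])
    )

    dmr_rows = []
    if config.n_dmrs and len(config.lines) >= 2:
        windows = []
        for c in chroms:
            L = len(genome.seqs[c])
            for s in range(0, L - config.dmr_size + 1, config.dmr_size):
                windows.append((c, s))
        take = rng.choice(len(windows), size=min(config.n_dmrs, len(windows)), replace=False)
        for w in sorted(take):
            c, s = windows[w]
            pair = rng.choice(len(config.lines), size=2, replace=False)
            dmr_rows.append({
                "chrom": c, "start": s, "end": s + config.dmr_size,
                "line_up": config.lines[pair[0]], "line_down": config.lines[pair[1]],
                "effect": config.dmr_effect,
            })
    dmr_truth = pd.DataFrame(
        dmr_rows, columns=["chrom", "start", "end", "line_up", "line_down", "effect"]
    )

    tfbs = ann.tfbs if ann.tfbs is not None else pd.DataFrame()
    tfbs_rows = []
    for line in config.lines:
        for si, t in tfbs.iterrows():
            motif_id = t["name"].split(":")[0]
            tfbs_rows.append({
                "line": line, "motif_id": motif_id, "site_index": si,
                "chrom": t["chrom"], "start": t["start"], "end": t["end"],
                "gene": t["gene"], "meth_state": int(rng.random() < 0.5),
            })
    tfbs_truth = pd.DataFrame(
        tfbs_rows,
        columns=["line", "motif_id", "site_index", "chrom", "start", "end", "gene", "meth_state"],
    )

    # probability maps ------------------------------------------------------
    probs: dict = {line: {1: {}, 2: {}} for line in config.lines}
    for c in chroms:
        ref_ok = ctx_ref[c]["context3"] >= 0
        base_shared = None if config.line_independent else _draw_base_probs(ctx_ref[c], rng, config)
        allele_base_shared = {}
        if not config.line_independent:
            for allele in (1, 2):
                ok = ctx_hap[allele][c]["context3"] >= 0
                arr = np.where(ok & ref_ok, base_shared, np.nan)
                new = ok & ~ref_ok
                if new.any():
                    fresh = _draw_base_probs(ctx_hap[allele][c], rng, config)
                    arr[new] = fresh[new]
                allele_base_shared[allele] = arr
        for line in config.lines:
            if config.line_independent:
                base = _draw_base_probs(ctx_ref[c], rng, config)
                allele_base = {}
                for allele in (1, 2):
                    ok = ctx_hap[allele][c]["context3"] >= 0
                    arr = np.where(ok & ref_ok, base, np.nan)
                    new = ok & ~ref_ok
                    if new.any():
                        fresh = _draw_base_probs(ctx_hap[allele][c], rng, config)
                        arr[new] = fresh[new]
                    allele_base[allele] = arr
                jitter = 0.0
            else:
                allele_base = allele_base_shared
                jitter = rng.normal(0.0, config.line_jitter, size=allele_base[1].shape) \
                    if config.line_jitter > 0 else 0.0
            for allele in (1, 2):
                probs[line][allele][c] = np.clip(allele_base[allele] + jitter, 0.0, 1.0)

    def _sites_in(c, start, end, allele, cg_only=True):
        c3 = ctx_hap[allele][c]["context3"]
        mask = np.zeros(c3.shape, dtype=bool)
        mask[:, start:end] = True
        if cg_only:
            mask &= c3 == 0
        else:
            mask &= c3 >= 0
        return mask

    # alternative-exon hypomethylation
    if ann.alt_exons is not None and len(ann.alt_exons) and config.alt_exon_meth_factor != 1.0:
        for _, e in ann.alt_exons.iterrows():
            for line in config.lines:
                for allele in (1, 2):
                    m = _sites_in(e["chrom"], e["start"], e["end"], allele, cg_only=False)
                    probs[line][allele][e["chrom"]][m] *= config.alt_exon_meth_factor

    # DMR windows (CG sites)
    for _, d in dmr_truth.iterrows():
        for allele in (1, 2):
            m = _sites_in(d["chrom"], d["start"], d["end"], allele, cg_only=True)
            up = probs[d["line_up"]][allele][d["chrom"]]
            up[m] = np.clip(up[m] + d["effect"], 0.0, 1.0)
            dn = probs[d["line_down"]][allele][d["chrom"]]
            dn[m] = np.clip(dn[m] - d["effect"], 0.0, 1.0)

    # ASM genes: allele 1 high, allele 2 low, at gene-body CG sites
    for _, g in asm_truth.iterrows():
        for line in config.lines:
            m1 = _sites_in(g["chrom"], g["start"], g["end"], 1, cg_only=True)
            m2 = _sites_in(g["chrom"], g["start"], g["end"], 2, cg_only=True)
            probs[line][1][g["chrom"]][m1] = config.asm_prob_high
            probs[line][2][g["chrom"]][m2] = config.asm_prob_low

    # TFBS instances: binary per-line methylation state at every cytosine
    for _, t in tfbs_truth.iterrows():
        for allele in (1, 2):
            m = _sites_in(t["chrom"], t["start"], t["end"], allele, cg_only=False)
            probs[t["line"]][allele][t["chrom"]][m] = float(t["meth_state"])

    return probs, dmr_truth, asm_truth, tfbs_truth


# ---------------------------------------------------------------------------
# Bisulfite reads
# ---------------------------------------------------------------------------

def simulate_bs_reads(
    haplotypes,
    probs_line: dict,
    config: SimulationConfig,
    rng: np.random.Generator,
    line: str,
) -> pd.DataFrame:
    """Sample post-alignment bisulfite reads for one cell line.

    Each read derives from one allele (uniform) and one bisulfite strand
    (uniform W/C), reported in plus-strand orientation. Cytosines of the
    fragment's strand are retained (methylated, Bernoulli of the true
    probability) or converted; with rate ``non_conversion_rate`` a whole
    read escapes conversion; sequencing errors are uniform substitutions.
    """
    hap1, hap2 = haplotypes
    rl = config.read_length
    chroms = list(hap1.seqs)
    lens = np.array([len(hap1.seqs[c]) for c in chroms])
    n_reads = int(np.ceil(config.coverage * lens.sum() / rl))
    chrom_idx = rng.choice(len(chroms), size=n_reads, p=lens / lens.sum())
    frames = []
    rid = 0
    for ci, chrom in enumerate(chroms):
        n = int((chrom_idx == ci).sum())
        if n == 0:
            continue
        L = lens[ci]
        starts = rng.integers(0, L - rl + 1, size=n)
        alleles = rng.integers(1, 3, size=n)
        bs = rng.random(n) < 0.5  # True -> W
        unconverted = rng.random(n) < config.non_conversion_rate
        cols = starts[:, None] + np.arange(rl)[None, :]
        seq = np.empty((n, rl), dtype=np.uint8)
        for allele, hap in ((1, hap1), (2, hap2)):
            sel = alleles == allele
            if not sel.any():
                continue
            codes = hap.codes(chrom)
            frag = codes[cols[sel]]
            p = probs_line[allele][chrom]
            for s_idx, w in ((0, True), (1, False)):
                sub = np.flatnonzero(sel)[bs[sel] == w]
                if sub.size == 0:
                    continue
                f = codes[cols[sub]]
                pr = np.nan_to_num(p[s_idx][cols[sub]], nan=0.0)
                site = f == (_C if w else _G)
                meth = rng.random(f.shape) < pr
                conv = site & ~meth & ~unconverted[sub, None]
                out = f.copy()
                out[conv] = _T if w else _A
                seq[sub] = out
        err = rng.random((n, rl)) < config.error_rate
        if err.any():
            shift = rng.integers(1, 4, size=int(err.sum())).astype(np.uint8)
            seq[err] = (seq[err] + shift) % 4
        df = pd.DataFrame({
            "read_id": [f"{line}:{chrom}:{i}" for i in range(n)],
            "chrom": chrom,
            "start": starts,
            "strand": np.where(bs, "+", "-"),
            "bs_strand": np.where(bs, "W", "C"),
            "seq": [codes_to_seq(row) for row in seq],
        })
        frames.append(df)
        rid += n
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["read_id", "chrom", "start", "strand", "bs_strand", "seq"]
    )


# ---------------------------------------------------------------------------
# RNA allele counts and expression
# ---------------------------------------------------------------------------

def simulate_rna_and_expression(
    annotations: AnnotationSet,
    snps: pd.DataFrame,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    tfbs_states: Optional[pd.DataFrame] = None,
):
    """RNA allele counts at exonic SNPs plus a gene-by-line expression table.

    ASE genes draw allele counts Binomial(n, bias) toward one haplotype,
    all others Binomial(n, 0.5). Gene expression is log-normal around a
    per-gene baseline; genes targeted by a methylation-sensitive motif are
    shifted on the log2 scale by effect x (per-line TFBS methylation
    state), plus Gaussian noise.

    Returns ``(rna_counts, expression, ase_truth)``.
    """
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    from .io_formats import exon_intervals

    genes = annotations.genes
    exons = exon_intervals(genes) if genes is not None and len(genes) else pd.DataFrame(
        columns=["gene_id", "chrom", "strand", "start", "end", "exon_index", "n_exons"]
    )

    # which SNPs are exonic, and in which gene
    snp_gene = []
    for _, s in snps.iterrows():
        hit = exons[
            (exons["chrom"] == s["chrom"])
            & (exons["start"] < s["pos"])
            & (s["pos"] <= exons["end"])
        ]
        for g in hit["gene_id"].unique():
            snp_gene.append({"chrom": s["chrom"], "pos": s["pos"], "ref": s["ref"],
                             "alt": s["alt"], "gene_id": g})
    exonic = pd.DataFrame(snp_gene, columns=["chrom", "pos", "ref", "alt", "gene_id"])

    with_snp = sorted(exonic["gene_id"].unique())
    n_ase = int(round(config.ase_fraction * len(with_snp)))
    ase_ids = sorted(rng.choice(with_snp, size=n_ase, replace=False)) if n_ase else []
    ase_truth = pd.DataFrame({
        "gene_id": ase_ids,
        "biased_hap": rng.integers(1, 3, size=len(ase_ids)),
        "bias": config.ase_bias,
    }, columns=["gene_id", "biased_hap", "bias"])
    bias_map = dict(zip(ase_truth["gene_id"], ase_truth["biased_hap"]))

    rna_rows = []
    for _, s in exonic.iterrows():
        n = config.rna_depth
        hap = bias_map.get(s["gene_id"])
        p1 = 0.5 if hap is None else (config.ase_bias if hap == 1 else 1 - config.ase_bias)
        k1 = int(rng.binomial(n, p1))
        rna_rows.append((s["chrom"], s["pos"], s["ref"], k1))
        rna_rows.append((s["chrom"], s["pos"], s["alt"], n - k1))
    rna_counts = pd.DataFrame(rna_rows, columns=["chrom", "pos", "allele", "count"])

    # expression: per-gene baseline (shared across lines) + motif effects
    gene_ids = list(genes["name"]) if genes is not None and len(genes) else []
    base = rng.normal(config.expr_base_mean, config.expr_base_sd, size=len(gene_ids))
    effects = {m[0]: m[2] for m in config.motifs}
    expr = {}
    for li, line in enumerate(config.lines):
        x = base.copy()
        if tfbs_states is not None and len(tfbs_states):
            sub = tfbs_states[tfbs_states["line"] == line]
            for _, t in sub.iterrows():
                eff = effects.get(t["motif_id"], 0.0)
                if eff and t["gene"] in gene_ids:
                    x[gene_ids.index(t["gene"])] += eff * t["meth_state"]
        x = x + rng.normal(0.0, config.expr_noise, size=len(gene_ids))
        expr[line] = np.maximum(np.exp2(x) - 1.0, 0.0)
    expression = pd.DataFrame(expr, index=pd.Index(gene_ids, name="gene_id"))
    return rna_counts, expression, ase_truth


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def simulate_all(config: SimulationConfig) -> SimResult:
    """Run the full generator with one seeded stream and return everything
    downstream stages need, including the planted truth."""
    rng = np.random.default_rng(config.seed)
    genome, ann = make_genome(config, rng)
    hap1, hap2, snps = make_diploid(genome, config, rng, annotations=ann)
    probs, dmr_truth, asm_truth, tfbs_truth = make_methylomes(
        genome, (hap1, hap2), config, rng, annotations=ann
    )
    reads = {
        line: simulate_bs_reads((hap1, hap2), probs[line], config, rng, line)
        for line in config.lines
    }
    rna_counts, expression, ase_truth = simulate_rna_and_expression(
        ann, snps, config, rng, tfbs_states=tfbs_truth
    )
    truth = TruthSet(
        snps=snps, ase_genes=ase_truth, asm_genes=asm_truth, dmrs=dmr_truth,
        tfbs_states=tfbs_truth, probs=probs,
        motif_effects=pd.DataFrame(
            list(config.motifs), columns=["motif_id", "tf_name", "effect"]
        ),
    )
    return SimResult(
        config=config, genome=genome, annotations=ann, haplotypes=(hap1, hap2),
        truth=truth, reads=reads, rna_counts=rna_counts, expression=expression,
    )


def write_simulation(sim: SimResult, outdir) -> None:
    """Serialize a simulation (FASTA, BEDs, read TSVs, expression, truth)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(sim.genome, outdir / "genome.fa")
    write_fasta(sim.haplotypes[0], outdir / "hap1.fa")
    write_fasta(sim.haplotypes[1], outdir / "hap2.fa")
    ann = sim.annotations
    write_bed(ann.genes, outdir / "genes.bed12", kind="bed12")
    write_bed(ann.cpg_islands, outdir / "cpg_islands.bed", kind="bed3")
    write_bed(ann.promoters, outdir / "promoters.bed", kind="bed6")
    write_bed(ann.alt_exons, outdir / "alt_exons.bed", kind="bed6")
    write_bed(ann.tfbs, outdir / "tfbs.bed", kind="tfbs")
    for line, reads in sim.reads.items():
        write_bsreads_tsv(reads, outdir / f"reads_{line}.tsv")
    sim.rna_counts.to_csv(outdir / "rna_allele_counts.tsv", sep="\t", index=False)
    write_expression_tsv(sim.expression, outdir / "expression.tsv")
    sim.truth.write(outdir / "truth")
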