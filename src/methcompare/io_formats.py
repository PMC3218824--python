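"""Readers and writers for the external formats the pipeline touches.

Conventions
-----------
* BED intervals are 0-based half-open, the dominant dialect for interval
  annotations (gene models, CpG islands, promoters, TFBSs).
* Per-cytosine methylation calls use 1-based positions (CGmap convention).
* Aligned bisulfite reads are ungapped and stored in reference (plus-strand)
  orientation; ``bs_strand`` records which genomic strand the original
  bisulfite-converted fragment derives from (``W`` = Watson/plus,
  ``C`` = Crick/minus) and therefore which strand's cytosines the read
  reports on.

All writers accept optional ``header_lines`` (emitted as ``#``-prefixed
comments) and all readers skip such comments, so provenance headers survive
round trips.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "GenomeSequence",
    "AnnotationSet",
    "read_fasta",
    "write_fasta",
    "read_methylome_tsv",
    "write_methylome_tsv",
    "read_bsreads_tsv",
    "write_bsreads_tsv",
    "read_bed",
    "write_bed",
    "exon_intervals",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gene_list",
    "write_gene_list",
]

_ALPHABET = set("ACGTN")

# byte -> small integer code used throughout the numeric layer
BASE_CODES = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
CODE_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)
_CODE_LUT = np.full(256, 4, dtype=np.uint8)
for _b, _c in BASE_CODES.items():
    _CODE_LUT[ord(_b)] = _c
    _CODE_LUT[ord(_b.lower())] = _c
# complement in code space: A<->T, C<->G, N->N
COMPLEMENT_CODE = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array (A=0, C=1, G=2, T=3, N=4)."""
    return _CODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def codes_to_seq(codes: np.ndarray) -> str:
    return CODE_BASES[codes].tobytes().decode("ascii")


@dataclass
class GenomeSequence:
    """A reference (or haplotype) genome: mapping of chromosome name to
    uppercase DNA, alphabet {A,C,G,T,N}."""

    seqs: dict[str, str]
    _codes: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        clean: dict[str, str] = {}
        for name, seq in self.seqs.items():
            seq = seq.upper()
            if len(seq) == 0:
                raise ValueError(f"empty sequence for chromosome {name!r}")
            extra = set(seq) - _ALPHABET
            if extra:
                raise ValueError(
                    f"chromosome {name!r} contains non-DNA characters {sorted(extra)!r}"
                )
            clean[name] = seq
        self.seqs = clean

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(s) for name, s in self.seqs.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.seqs.values())

    def codes(self, chrom: str) -> np.ndarray:
        """Cached uint8 encoding of one chromosome."""
        arr = self._codes.get(chrom)
        if arr is None:
            arr = seq_to_codes(self.seqs[chrom])
            self._codes[chrom] = arr
        return arr

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.seqs

    def __iter__(self):
        return iter(self.seqs)


@dataclass
class AnnotationSet:
    """Interval annotations used downstream.

    ``genes`` is a BED12 table (one row per gene model, exon blocks kept as
    lists); the optional members are BED3/BED6 tables. TFBS names follow the
    ``motifID:TFname`` convention with the assigned gene in an extra column.
    """

    genes: Optional[pd.DataFrame] = None
    cpg_islands: Optional[pd.DataFrame] = None
    promoters: Optional[pd.DataFrame] = None
    alt_exons: Optional[pd.DataFrame] = None
    tfbs: Optional[pd.DataFrame] = None


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> GenomeSequence:
    """Read a (multi-record) FASTA into a :class:`GenomeSequence`.

    Sequences are uppercased; ``N`` is allowed. Duplicate record names and
    empty records are errors.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate chromosome name {rec.id!r} in {path}")
        if len(rec.seq) == 0:
            raise ValueError(f"empty FASTA record {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise ValueError(f"no FASTA records found in {path}")
    return GenomeSequence(seqs)


def write_fasta(genome: GenomeSequence, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Methylome TSV (CGmap-style dialect)
# ---------------------------------------------------------------------------

METHYLOME_COLUMNS = [
    "chrom",
    "pos",
    "strand",
    "context3",
    "dinuc",
    "meth_count",
    "total_count",
    "is_tacag",
]

_CONTEXT3 = {"CG", "CHG", "CHH"}
_DINUC = {"CG", "CA", "CC", "CT"}


def _open_skip_comments(path):
    lines = []
    numbers = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            lines.append(line)
            numbers.append(i)
    return lines, numbers


def read_methylome_tsv(path) -> pd.DataFrame:
    """Read per-cytosine methylation calls.

    Columns: chrom, pos (1-based), strand, context3, dinuc, meth_count,
    total_count, is_tacag (0/1). Rows are returned sorted by
    (chrom, pos, strand); a row with meth_count > total_count is rejected
    with the offending line named.
    """
    lines, numbers = _open_skip_comments(path)
    if not lines:
        return pd.DataFrame(columns=METHYLOME_COLUMNS)
    df = pd.read_csv(
        io.StringIO("".join(lines)),
        sep="\t",
        header=None,
        names=METHYLOME_COLUMNS,
        dtype={
            "chrom": str,
            "pos": np.int64,
            "strand": str,
            "context3": str,
            "dinuc": str,
            "meth_count": np.int64,
            "total_count": np.int64,
            "is_tacag": np.int64,
        },
    )
    bad = df["meth_count"] > df["total_count"]
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"{path} line {numbers[i]}: meth_count exceeds total_count"
        )
    if not df["strand"].isin(["+", "-"]).all():
        raise ValueError(f"{path}: strand must be '+' or '-'")
    if not df["context3"].isin(_CONTEXT3).all():
        raise ValueError(f"{path}: context3 must be one of {sorted(_CONTEXT3)}")
    if not df["dinuc"].isin(_DINUC).all():
        raise ValueError(f"{path}: dinuc must be one of {sorted(_DINUC)}")
    if (df["meth_count"] < 0).any():
        raise ValueError(f"{path}: negative counts")
    df["is_tacag"] = df["is_tacag"].astype(bool)
    df = df.sort_values(["chrom", "pos", "strand"], kind="mergesort")
    return df.reset_index(drop=True)


def write_methylome_tsv(table: pd.DataFrame, path, header_lines: Sequence[str] = ()) -> None:
    if (table["meth_count"] > table["total_count"]).any():
        raise ValueError("meth_count exceeds total_count")
    out = table.loc[:, METHYLOME_COLUMNS].copy()
    out["is_tacag"] = out["is_tacag"].astype(int)
    out = out.sort_values(["chrom", "pos", "strand"], kind="mergesort")
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        out.to_csv(fh, sep="\t", header=False, index=False)


def methylation_level(table: pd.DataFrame) -> pd.Series:
    """Per-site level = meth_count / total_count (NaN where uncovered)."""
    total = table["total_count"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        lev = table["meth_count"].to_numpy(dtype=float) / total
    return pd.Series(np.where(total > 0, lev, np.nan), index=table.index, name="level")


# ---------------------------------------------------------------------------
# Aligned bisulfite reads TSV
# ---------------------------------------------------------------------------

BSREAD_COLUMNS = ["read_id", "chrom", "start", "strand", "bs_strand", "seq"]


def read_bsreads_tsv(path, genome: Optional[GenomeSequence] = None) -> pd.DataFrame:
    """Read aligned, ungapped bisulfite reads (order preserved).

    If ``genome`` is supplied, reads extending past a chromosome end are
    rejected.
    """
    lines, numbers = _open_skip_comments(path)
    if not lines:
        return pd.DataFrame(columns=BSREAD_COLUMNS)
    df = pd.read_csv(
        io.StringIO("".join(lines)),
        sep="\t",
        header=None,
        names=BSREAD_COLUMNS,
        dtype={
            "read_id": str,
            "chrom": str,
            "start": np.int64,
            "strand": str,
            "bs_strand": str,
            "seq": str,
        },
    )
    if not df["strand"].isin(["+", "-"]).all():
        raise ValueError(f"{path}: strand must be '+' or '-'")
    if not df["bs_strand"].isin(["W", "C"]).all():
        raise ValueError(f"{path}: bs_strand must be 'W' or 'C'")
    if (df["start"] < 0).any():
        raise ValueError(f"{path}: negative start")
    if genome is not None:
        lens = genome.lengths
        ends = df["start"].to_numpy() + df["seq"].str.len().to_numpy()
        limit = df["chrom"].map(lens)
        if limit.isna().any():
            bad = df.loc[limit.isna(), "chrom"].iloc[0]
            raise ValueError(f"{path}: unknown chromosome {bad!r}")
        over = ends > limit.to_numpy()
        if over.any():
            i = int(np.flatnonzero(over)[0])
            raise ValueError(
                f"{path} line {numbers[i]}: read exceeds chromosome bounds"
            )
    return df


def write_bsreads_tsv(reads: pd.DataFrame, path, header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        reads.loc[:, BSREAD_COLUMNS].to_csv(fh, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

BED12_COLUMNS = [
    "chrom", "start", "end", "name", "score", "strand",
    "thick_start", "thick_end", "item_rgb", "block_count",
    "block_sizes", "block_starts",
]


def _parse_int_list(text: str) -> list[int]:
    return [int(x) for x in str(text).rstrip(",").split(",") if x != ""]


def read_bed(path, kind: str = "bed3") -> pd.DataFrame:
    """Read a BED3/BED6/BED12 (or TFBS = BED6 + gene column) file.

    Intervals are 0-based half-open; ``end <= start`` is an error, and for
    BED12 the block structure must be internally consistent.
    """
    lines, numbers = _open_skip_comments(path)
    ncols = {"bed3": 3, "bed6": 6, "bed12": 12, "tfbs": 7}[kind]
    rows = []
    for line, lineno in zip(lines, numbers):
        parts = line.rstrip("\n").split("\t")
        if len(parts) < ncols:
            raise ValueError(f"{path} line {lineno}: expected {ncols} columns")
        chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        if end <= start:
            raise ValueError(f"{path} line {lineno}: end <= start")
        if start < 0:
            raise ValueError(f"{path} line {lineno}: negative start")
        if kind == "bed3":
            rows.append((chrom, start, end))
            continue
        name, score, strand = parts[3], parts[4], parts[5]
        if strand not in ("+", "-", "."):
            raise ValueError(f"{path} line {lineno}: bad strand {strand!r}")
        if kind == "bed6":
            rows.append((chrom, start, end, name, score, strand))
        elif kind == "tfbs":
            rows.append((chrom, start, end, name, float(score), strand, parts[6]))
        else:  # bed12
            block_count = int(parts[9])
            sizes = _parse_int_list(parts[10])
            starts = _parse_int_list(parts[11])
            if len(sizes) != block_count or len(starts) != block_count:
                raise ValueError(
                    f"{path} line {lineno}: blockSizes/blockStarts do not match blockCount"
                )
            if starts[0] != 0 or start + starts[-1] + sizes[-1] != end:
                raise ValueError(
                    f"{path} line {lineno}: block structure inconsistent with start/end"
                )
            for bs, sz in zip(starts, sizes):
                if sz <= 0 or start + bs + sz > end:
                    raise ValueError(f"{path} line {lineno}: block outside record")
            rows.append(
                (chrom, start, end, name, score, strand,
                 int(parts[6]), int(parts[7]), parts[8], block_count, sizes, starts)
            )
    columns = {
        "bed3": ["chrom", "start", "end"],
        "bed6": ["chrom", "start", "end", "name", "score", "strand"],
        "tfbs": ["chrom", "start", "end", "name", "score", "strand", "gene"],
        "bed12": BED12_COLUMNS,
    }[kind]
    df = pd.DataFrame(rows, columns=columns)
    if kind == "tfbs" and len(df):
        if not df["name"].str.contains(":").all():
            raise ValueError(f"{path}: TFBS names must parse as 'motifID:TFname'")
    return df


def write_bed(df: pd.DataFrame, path, kind: str = "bed3", header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        for _, row in df.iterrows():
            if kind == "bed3":
                fields = [row["chrom"], row["start"], row["end"]]
            elif kind == "bed6":
                fields = [row[c] for c in ["chrom", "start", "end", "name", "score", "strand"]]
            elif kind == "tfbs":
                fields = [row[c] for c in ["chrom", "start", "end", "name", "score", "strand", "gene"]]
            else:
                fields = [
                    row["chrom"], row["start"], row["end"], row["name"], row["score"],
                    row["strand"], row["thick_start"], row["thick_end"], row["item_rgb"],
                    row["block_count"],
                    ",".join(str(x) for x in row["block_sizes"]),
                    ",".join(str(x) for x in row["block_starts"]),
                ]
            fh.write("\t".join(str(f) for f in fields) + "\n")


def exon_intervals(genes: pd.DataFrame) -> pd.DataFrame:
    """Explode BED12 gene models into one row per exon block.

    Returns columns gene_id, chrom, strand, start, end, exon_index,
    n_exons; exon_index counts along the coding strand (0 = first exon of
    the transcript).
    """
    rows = []
    for _, g in genes.iterrows():
        n = g["block_count"]
        for i, (bs, sz) in enumerate(zip(g["block_starts"], g["block_sizes"])):
            idx = i if g["strand"] == "+" else n - 1 - i
            rows.append(
                (g["name"], g["chrom"], g["strand"], g["start"] + bs, g["start"] + bs + sz, idx, n)
            )
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "strand", "start", "end", "exon_index", "n_exons"]
    )


# ---------------------------------------------------------------------------
# Expression tables and gene lists
# ---------------------------------------------------------------------------

def read_expression_tsv(path) -> pd.DataFrame:
    """Gene-by-cell-line expression: header row with line names, a gene_id
    column, non-negative real values."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: missing 'gene_id' column")
    value_cols = [c for c in df.columns if c != "gene_id"]
    if not value_cols:
        raise ValueError(f"{path}: no cell-line columns")
    if (df[value_cols] < 0).any().any():
        raise ValueError(f"{path}: negative expression values")
    return df.set_index("gene_id")


def write_expression_tsv(expr: pd.DataFrame, path, header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        expr.reset_index().rename(columns={"index": "gene_id"}).to_csv(
            fh, sep="\t", index=False
        )


def read_gene_list(path) -> list[str]:
    """Plain-text gene list, one identifier per line."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def write_gene_list(genes: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")
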