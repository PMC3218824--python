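# Methods

`methcompare` implements a comparative analysis of whole-genome bisulfite
methylomes from multiple cell lines. This note records the models, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical decisions a maintainer would want to
know about.

## Methylation calling

Bisulfite conversion leaves methylated cytosines as C and turns
unmethylated cytosines into T (read-level). A Watson-strand fragment
(`bs_strand = W`) therefore reports plus-strand cytosines; a Crick
fragment reports minus-strand cytosines, which in plus-strand
orientation appear as G (methylated) vs A (converted). The methylation
level of a cytosine is `meth / (meth + unmeth)` over reads of the
matching bisulfite strand; read bases other than the methylated or
converted base (errors, SNPs) count toward neither.

*Non-conversion filter.* A read showing more than two consecutive
methylated non-CG cytosines — consecutive among the read's non-CG
cytosine positions, CG sites skipped, regardless of genomic gaps — is
treated as an unconverted molecule and discarded. The read-order
definition matches the read-level failure mode (a whole molecule escapes
conversion), which is also how the generator simulates it (a read is
fully unconverted with rate 0.005 by default).

*Context labels.* `CG`, `CHG`, `CHH` from the two on-strand downstream
bases; the summary table also pools the non-CG dinucleotide classes
`CA/CC/CT`, the `CAG` trinucleotide subclass (CHG with downstream A),
and the `TACAG` 5-mer subclass. The classes overlap deliberately: every
TACAG site is also a CAG, CHG and CA site. Global levels are the
unweighted mean of per-site levels over sites with coverage >= 4
(minimum coverage configurable); a read-pooled mode
(sum meth / sum total) is available behind a flag, because the
site-averaged reading of "mean over cytosines" is an interpretation —
both are exposed, site-averaged is the default. Chromosome-edge
cytosines with fewer than two downstream bases get context `NA` and are
excluded everywhere.

## Conservation and symmetry

Levels are binned: CG into low (rounded percent <= 33), medium (34-66)
and high (>= 67); non-CG into none (zero methylated reads), low
(level <= 0.30) and high (> 0.30). Rounded-percent binning makes the
integer bin edges partition exactly. Pairwise 3x3 contingency tables are
compared against the independence null (outer product of margins) as
fold enrichments; a site is conserved when it falls in the same bin in
both lines. Sites covered in one line but not the other are excluded.
Non-CG sites are classified over all lines jointly: `conserved_high`
(high everywhere), `unconserved_methylated` (high in exactly one line,
none in every other — the strict reading of "methylated in one,
unmethylated in the others"), `unmethylated` (none everywhere).

Strand symmetry pairs the plus-strand C of a CG dyad with the minus-
strand C one base downstream (for CHG, two bases downstream). The 2x2
factor is "any methylated read" (level > 0) by default, with low
(< 0.30) and high (> 0.30) strata reusing the non-CG bin boundary; the
reported symmetric fraction counts dyads with both strands in the
methylated (or in-stratum) state.

## DMRs

Chromosomes are tiled into 1-kb windows; a window's level is the
unweighted mean of its covered CG (or CHG) sites, missing below 5 sites
(ratios over fewer sites are dominated by counting noise). For a pair of
lines, `r = (higher + eps) / (lower + eps)` with pseudocount
`eps = 0.01` to avoid division by zero; `z` standardizes `r` over all
jointly scored windows (raw ratios, not logs — a log mode exists behind
a flag) and `z > 2` flags a DMR. Conserved DMRs are windows flagged in
all three pairwise comparisons. The FDR of the conserved fraction is
estimated by shuffling each line's window-mean vector genome-wide
(preserving its multiset, asserted per permutation), re-running the
full call, and dividing the mean null conserved fraction by the observed
one; 300 permutations by default. Feature enrichment is base-pair fold
enrichment against promoter (TSS +- 1 kb; the promoter definition is
ours), exon, intron, CpG island, and shore (2-kb island flanks minus
islands).

## SNP calling and allele-specific expression

Because bisulfite chemistry collapses C with T, read C/T observations at
a reference C — and, symmetrically, plus-strand G/A observations at a
reference G — are excluded from allele evidence from all reads. A het
whose two alleles are exactly that ambiguous pair is structurally
uncallable from bisulfite data. Per-allele counts are the average of the
per-alignment-strand tallies; a het call needs included coverage >= 8,
the two main alleles covering > 75% of included reads, and a count
difference within 20% of their sum (major-allele ratio <= 0.6). The
balance rule is strict: at 30x depth it accepts a true balanced het with
probability ~0.74 (exact binomial computation), so recall against
planted truth plateaus near that value — an inherent property of the
filter itself, not of the implementation; raising depth to ~80x lifts it above
0.9.

Exonic SNPs are het calls inside exon blocks with >= 4 RNA reads over
the two alleles; the RNA-major allele is defined per SNP and per-SNP
major counts are summed per gene (a haplotype-consistent mode would
require phasing RNA alleles and is deliberately not the default). The
gene-level test is an exact two-sided binomial (minimum-likelihood
convention: sum of all outcome probabilities not exceeding the observed
one) against p0 = 0.5, thresholded by Benjamini-Hochberg at 1% FDR; the
calibrated threshold is reported so a fixed genome-wide cutoff (such as
0.0027) has a computable analog. Imprinted-gene enrichment is an
upper-tail hypergeometric over the testable universe.

## Allele-specific methylation and phasing

Reads spanning a het SNP are segregated by the allele they show;
observations that could be a conversion product of an allele (C on the
read's own bisulfite strand) stay unassigned, so Crick reads can resolve
a C/T SNP that Watson reads cannot. Per candidate CG cytosine covered by
both allele groups, the level estimated from one group (unsmoothed,
degenerate 0/1 handled as a point mass) parameterizes an exact two-sided
binomial on the other group's counts; the test is repeated with groups
swapped and the larger p kept, making the statistic symmetric in the
labels. BH at 5% FDR across all tested cytosines. A site linked to
several SNPs is tested once against the deepest-covering SNP, keeping
each test haplotype-consistent (reads are assigned per anchor SNP; the
alternative of pooling across SNPs would need SNP-SNP phasing).
Gene-level enrichment — the count of significant among tested sites in a
gene body against the genome-wide significant rate, upper-tail binomial,
BH at 5% — is our own calibrated choice; only "enrichment" itself is
given, no formula. Phasing reports, per allele, the methylated fraction
at every CG site sharing a read with the SNP, in genomic order; pooled
intermediate levels at such sites resolve into near-0/near-1 per-allele
patterns when allele-specific methylation is real.

## TFBS methylation sensitivity

Per binding site and line, methylation is the unweighted mean of covered
CG cytosines in the interval; the neighborhood is +-500 bp excluding the
site. For a line pair, per-motif Pearson correlation of
`dm = m_B - m_A` against `de = log2(e_B + 1) - log2(e_A + 1)` over sites
with `|dm| >= 0.1` ("differential methylation observed"; the threshold
is configurable down to > 0, no value being given). Expression deltas on
log2(x+1); raw scale behind a flag. A motif passes with >= 10 scored
sites and p < 0.05, and is methylation-sensitive when `|r_site|` also
exceeds `|r_neighbor|`. Site-to-gene assignment comes from the TFBS
file's gene column (nearest-TSS fallback within 10 kb); multiple motifs
of one TF stay separate; correlations are per site by default with a
per-gene deduplicated mode.

## The synthetic generator

The generator is first-class, tested code: it defines the study
conditions under which every recovery claim is measured.

What it emulates, with defaults:

- **Genome** (140 kb over two chromosomes by default): random sequence at
  GC 0.42; 40 multi-exon genes whose introns start with `GT` and end
  with the canonical `CAG` acceptor (half of them as the full `TACAG`);
  CpG-island sequence at 60% of promoters; TFBS motif instances (each
  containing a CG) upstream of disjoint target genes; TACAG 5-mers
  scattered at 20/kb. The density is deliberately high: an analytic
  calculation over the prescribed Beta tails and binomial coverage noise
  shows the conserved-high non-CG class is then >= 90% TACAG at depths
  5-20, which is the regime the motif-recovery analysis needs. A real
  genome is far sparser in the motif; the purity number, not the motif
  count, is the transferable observation.
- **Diploid**: het SNPs at 1e-3/bp, hap1 = reference, hap2 = alternate;
  25% on C/G reference positions as C>T / G>A transitions (the
  bisulfite-ambiguous class), the rest A<->T. Transversions that create
  or destroy cytosines are not simulated: conversion chemistry leaves
  such sites partially visible and they fail the balance filter for
  reasons unrelated to anything under test (a documented limitation —
  real data contain them and real recall is correspondingly lower).
- **Methylation**: CG dyads from 0.25*Beta(1,9) + 0.75*Beta(9,1)
  (bimodal), sharing one probability across strands for 77% of dyads;
  non-CG from Beta(0.5,15); TACAG cytosines from a Beta with mean 0.22
  (concentration 10). All lines share one base map up to N(0, 0.02)
  jitter; a `line_independent` switch redraws everything per line for
  null analyses. Planted on top, in order: alternative-exon
  hypomethylation (x0.4), 12 DMR windows of 1 kb (one line +0.4, another
  -0.4, CG sites; 12 windows keeps the recall estimate stable across
  seeds by a pre-registered power calculation), ASM genes (15% of genes;
  allele 1 -> 0.9, allele 2 -> 0.1, gap 0.8), and per-line binary (0/1)
  methylation states at TFBS instances — binary states make noise-free
  site methylation exactly recoverable from reads.
- **Reads**: 30x single-end 75-mers, allele and bisulfite strand uniform,
  per-read full non-conversion at 0.5%, uniform substitution errors at
  0.2%, emitted pre-aligned in plus-strand orientation.
- **RNA/expression**: fixed 60 reads per exonic SNP, Binomial(n, 0.9)
  toward one haplotype for 20% ASE genes, Binomial(n, 0.5) otherwise;
  gene expression log-normal (log2 baseline N(5, 1.5)) shifted by
  (motif effect) x (site methylation state) with N(0, 0.25) log2 noise.

What it does not emulate — and hence what passing tests do not show
about real data: alignment and mapping bias (reads are born aligned),
indels, paired ends, quality scores, PCR duplicates, M-bias,
CNVs/aneuploidy (common in cultured ESC lines), realistic linkage
between SNPs, cell-population heterogeneity beyond the Beta noise model,
and chromatin context. Recovery rates here are upper bounds on what the
same thresholds achieve on real libraries.

## Numerical choices and degenerate inputs

- Exact tests use scipy probability mass functions with a 1e-9 relative
  tie guard for the minlike two-sided sum; enumeration oracles in the
  test suite confirm agreement to 1e-12 for all n <= 20.
- `call_dmrs` refuses fewer than 30 jointly scored windows or a
  degenerate (zero-sd) ratio distribution; `permutation_fdr` reports a
  missing FDR when the observed conserved fraction is zero.
- Empty classes (no alternative exons, a context with no qualifying
  site, an uncovered TFBS) are reported missing (NaN / absent), never
  zero; empty site sets and empty region sets are errors.
- Coordinates: BED intervals 0-based half-open; cytosine positions and
  SNPs 1-based. Ties in the CG percent bins are settled by half-up
  rounding so the printed integer edges partition exactly.
- All simulation randomness flows from a single `numpy` Generator seeded
  by the config; identical configs give byte-identical outputs.

## Problem sizes

Analyses in the test suite and the reproduction script run on 40-190 kb
genomes at 10-50x — sizes at which every stage's statistics are already
well-populated (thousands of CG dyads, hundreds of windows, dozens of
planted effects) while the whole suite stays interactive. All window,
coverage and FDR parameters are the same ones a genome-scale run would
use.

## Known limitations

- The SNP caller's strict balance filter caps het recall near 0.74 at
  30x (see above); this is the rule working as defined.
- Conserved DMRs require all three pairwise calls to fire; with planted
  two-line shifts the third pairwise contrast is weaker, so the
  conserved set is often empty in synthetic runs and the permutation FDR
  is then undefined (reported missing).
- Gene-level ASM enrichment and the ASM anchor-SNP policy are calibrated
  inventions where only the intent is specified; both are documented
  above and configurable.
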