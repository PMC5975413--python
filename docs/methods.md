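# Methods

## Model and assumptions

`homogene` maps annotated protein-coding genes from a reference genome onto
a related target genome. It relies on two signals that decay slowly with
evolutionary distance: the amino-acid sequence of the protein, and the
positions of introns within the coding sequence (exon–exon boundaries in
the CDS tend to sit at homologous protein positions in orthologs).
Optional RNA-seq alignments of the target species add direct experimental
splice sites. The approach assumes colinear exon order within a single
target sequence, the standard genetic code, and canonical (GT/GC..AG)
splicing wherever no experimental evidence overrides it. Genes without a
homolog in the reference cannot be predicted.

Coordinates are 0-based half-open internally; GFF3 I/O converts to 1-based
inclusive. Coding parts of a transcript are held in translation order with
GFF3-style phases; codons split across an intron are attributed to the
part containing at least two of the codon's bases when per-part peptides
are built (the convention is a package choice; any fixed convention only
shifts single boundary residues between neighboring peptides).

## Pipeline stages

**Evidence extraction (ERE).** Each N operation in a spliced alignment's
CIGAR whose span lies within the intron size bounds contributes one
split-read observation of an intron; identical observations merge with
summed counts. Intron strand comes from the aligner's XS tag when present,
else from boundary dinucleotides when a genome is supplied, else it is
`unknown` and usable on both strands. Coverage counts M/=/X segments only
and is strand-agnostic (unstranded libraries supported). Introns may be
filtered by a minimum split-read count (default 1).

**Homology search.** Every part peptide is aligned by local
Smith–Waterman (BLOSUM62, gap open 11, gap extend 1, BLAST-style cost
`11 + k` for a length-k gap) against all six reading frames of every
target sequence; hits scoring at least `min_score_fraction` (default 0.3)
of the peptide's self-score are reported, iterating with masking so
multiple loci per frame are found. Part peptides shorter than 8 aa are
searched jointly with a neighbor and logged. The search is exhaustive and
intended for desk-scale genomes; for large genomes externally computed
hits can be imported in the common 12-column tabular format (query ids
`<transcript_id>|<part_index>`).

**Assembly.** Hits are chained colinearly per (sequence, strand) by
dynamic programming (gap between consecutive parts within intron bounds,
with a small allowance for anchor overshoot); chains are extracted
greedily by score without hit reuse. Minus-strand chains are mirrored
into the reverse-complement coordinate frame so all junction arithmetic
is plus-strand. For each neighboring exon pair, donor candidates are
collected within ±30 nt of the upstream anchor (±60 on retry) and
acceptor candidates around the downstream anchor — experimental sites
exclusively when any exist in the window, conserved dinucleotides
otherwise. Every (donor, acceptor) pair with an in-bounds intron length
whose combined exon length change keeps the join in frame is scored by
translating the junction region and aligning it, end-gap free, to the
reference peptide context around the corresponding reference intron
(16 aa per side). End-gap-free (overlap) alignment is essential here:
the translated window and the reference context do not correspond
exactly at their outer ends, and penalized end gaps would systematically
favor boundary shifts of one codon. Ties prefer experimental evidence,
then minimal deviation of the intron position from the reference
position (measured against the alignment anchors), then the leftmost
donor. An unresolved junction truncates the model there.

Terminal adjustment searches in-frame ATGs within ±90 nt of the aligned
start (candidates may not introduce an upstream in-frame stop; among
several, the one maximizing the protein's global alignment score against
the reference wins, then the nearest). The stop codon is found by
truncating at the first in-frame stop inside the model, or scanning up to
67 codons downstream of the last aligned codon. Models that gain both an
ATG start and a stop end are flagged complete; proteins never contain `*`.

Each model is scored by global alignment of its protein against the
reference protein (same matrix and gaps); this score, divided by protein
length, is the relative score used for filtering. Up to k (default 10)
ranked predictions per reference transcript are returned unfiltered.

**Evidence statistics.** An intron counts as supported only when both
boundaries match an evidence intron exactly (deliberately no near-miss
tolerance: split reads define introns at base precision); `unknown`-strand
evidence supports either strand. tie/tae/tde are fractions over the
predicted introns (NA for single-coding-exon models); tpc counts coding
bases with coverage ≥ 1 (no depth parameter); minSplitReads is NA if any
intron is unsupported. pAA/iAA are percentages over all columns (gap
columns included in the denominator) of the global protein alignment.

**Annotation filter (GAF).** Order of operations: relative-score filter
(default threshold 0.75) → merge border-identical predictions, also
across reference species, counting distinct supporting species as
`evidence` → optional minimum-evidence and completeness filters (both off
by default) → same-strand overlap clustering (connected components,
≥ 1 shared base) → per cluster, the highest-scoring member is the
representative (ties: longer coding region, leftmost, lexicographic id);
other members sharing at least the common-border fraction (default 0.75,
computed relative to the smaller border set of the pair) of borders with
the representative are kept as alternative transcripts; border-identical
members are dropped into the `alternative` attribute; discarded members
overlapping no kept prediction *at the coding-exon level* are recovered
recursively as nested genes (span-level overlap would make recovery of
intron-nested genes impossible). Kept transcripts get generic gene names
in coordinate order.

**Evaluation.** All levels compare CDS coordinates only. An exon is
correct iff an annotated part with identical (sequence, strand, start,
end) exists; duplicate coordinate sets count once in denominators. A
transcript is correct iff its full part set is coordinate-identical. An
annotated gene is found iff any of its transcripts is correct; a
predicted gene is correct iff any of its transcripts matches (a gene with
one matching and one wrong transcript counts as correct, a documented
package choice). F1 is the harmonic mean of Sn and Sp; empty denominators
yield NA. Best-overlap assignment maximizes the F1 of shared coding bases
(ties: more shared bases, then lexicographic id).

## Synthetic test bed

The generator emulates the intended use case at desk scale: by default 20
genes with 2–8 exons of 33–150 nt, introns of 40–300 nt (within the
25 bp–15 kb bounds applied at extraction), ~50 % of genes on the minus
strand, random intergenic spacers of 200–500 nt, intron positions at
arbitrary base offsets so all three phases occur. The target is derived
by codon-level substitution to a requested protein identity (default
0.9 — a moderately diverged congener; start/stop untouched, no stops
introduced, 10 % silent codon changes), optional ±1-codon intron shifts,
and regenerated intron interiors. Simulated RNA-seq spans every intron
with (default) 2 split reads of 50 nt carrying exact N CIGARs and XS
tags, and tiles exons so every coding base is covered.

What the fixtures do **not** model: sequencing/mapping error, paired
ends, expression heterogeneity, repeats, pseudogenes, gene family
expansions, unstranded or noisy splice evidence beyond decoys added in
unit tests, and genome-scale inputs. Passing tests therefore demonstrate
algorithmic correctness of extraction, search, assembly, statistics,
filtering and evaluation — not performance on real assemblies, where the
exhaustive search would also need to be replaced by imported hits.

## Numerical choices and degenerate inputs

* Gap model: BLAST-style affine costs mapped onto Biopython's
  `PairwiseAligner` (open = −12, extend = −1); all alignment stages share
  it for comparability of scores.
* Chaining allows anchor overshoot of up to 24 nt below the minimum
  intron length; splice windows are ±30 nt, widened once to ±60.
* Junction scoring windows: ≤ 48 nt of coding sequence per side,
  codon-aligned upstream; reference context 16 aa per side taken from the
  per-part peptides (this also handles chains that skip an unmatched
  part).
* Empty alignments score 0; empty prediction sets evaluate to NA rather
  than 0; headerless SAM gets a synthesized header (pysam requires @SQ).
* Frame bookkeeping is exact across split codons: the in-frame test for a
  junction is `(coding_length_so_far + (downstream_anchor − acceptor)) ≡ 0
  (mod 3)` against the downstream hit's codon grid, not a naive equality
  of length changes.
* Determinism: one `numpy` Generator per operation, seeded explicitly;
  ranking and tie-breaks are total orders, so outputs are reproducible.

## Known limitations

Single-contig models only (chains never cross sequence boundaries); no
UTR/exon features, GTF, or alternative genetic codes; merged-search hits
for sub-8-aa parts are approximate; the exhaustive six-frame search
scales as (proteome × genome) and is not meant for hundreds of megabases;
the relative-score and common-border defaults (both 0.75) are exposed on
the CLI and should be tuned per application.
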