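"""Deterministic synthetic test bed.

Generates a reference genome with annotated multi-exon protein-coding
genes (ATG start, stop end, canonical GT..AG introns, mixed strands), a
diverged target genome with known orthologous gene models obtained by
codon-level mutation of each reference gene, and simulated spliced
RNA-seq alignments whose split reads span every intron of the truth
annotation. Everything is reproducible from the seed.

The generator emulates the situation the predictor is built for — a
well-annotated reference and a related target at a chosen protein
identity — but not sequencing error, paired ends, expression
heterogeneity, repeats or pseudogenes.
"""

from __future__ import annotations

import os

import numpy as np

from .genome_io import (GenomeSequences, ReferenceTranscript, build_transcript,
                        reverse_complement, write_fasta, write_reference_gff3)

_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")
_NON_STOP_CODONS = tuple(a + b + c
                         for a in _BASES for b in _BASES for c in _BASES
                         if a + b + c not in _STOPS)

_AA_OF = {}
_CODONS_OF: dict[str, list[str]] = {}
from Bio.Seq import Seq as _Seq  # noqa: E402

for _codon in _NON_STOP_CODONS:
    _aa = str(_Seq(_codon).translate())
    _AA_OF[_codon] = _aa
    _CODONS_OF.setdefault(_aa, []).append(_codon)
_AMINO_ACIDS = sorted(_CODONS_OF)

DEFAULT_N_GENES = 20
DEFAULT_EXONS_PER_GENE = (2, 8)
DEFAULT_EXON_LEN = (33, 150)
DEFAULT_INTRON_LEN = (40, 300)
DEFAULT_SPACER_LEN = (200, 500)
DEFAULT_AA_IDENTITY = 0.9
DEFAULT_READS_PER_INTRON = 2
DEFAULT_READ_LEN = 50
_SYNONYMOUS_PROB = 0.1

CONTIG = "chr1"


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_BASES), size=length))


def _random_intron(rng: np.random.Generator, length: int) -> str:
    return "GT" + _random_dna(rng, length - 4) + "AG"


def _assemble_contig(rng, gene_payloads: list[tuple[str, str, list[tuple[int, int]]]],
                     spacer_len: tuple[int, int]):
    """Concatenate genes with random spacers; returns contig and parts.

    ``gene_payloads`` holds (sense_gene_seq, strand, sense_exon_intervals);
    returned exon intervals are genomic (contig) 0-based half-open.
    """
    pieces = []
    offset = 0
    placed = []
    for sense_seq, strand, sense_exons in gene_payloads:
        spacer = _random_dna(rng, int(rng.integers(spacer_len[0], spacer_len[1] + 1)))
        pieces.append(spacer)
        offset += len(spacer)
        glen = len(sense_seq)
        if strand == "+":
            pieces.append(sense_seq)
            exons = [(offset + a, offset + b) for a, b in sense_exons]
        else:
            pieces.append(reverse_complement(sense_seq))
            exons = [(offset + glen - b, offset + glen - a) for a, b in sense_exons]
            exons.sort()
        placed.append((strand, exons))
        offset += glen
    tail = _random_dna(rng, int(rng.integers(spacer_len[0], spacer_len[1] + 1)))
    pieces.append(tail)
    return "".join(pieces), placed


def _build_transcripts(genome: GenomeSequences, placed, prefix: str = "g"):
    from .genome_io import CodingPart

    transcripts = []
    for i, (strand, exons) in enumerate(placed):
        gene_id = f"{prefix}{i:03d}"
        parts = [CodingPart(CONTIG, a, b, strand) for a, b in exons]
        t = build_transcript(f"{gene_id}.t1", gene_id, parts, genome)
        if t is None:
            raise AssertionError("generated gene unexpectedly contains a stop codon")
        transcripts.append(t)
    return transcripts


def generate_reference(n_genes: int = DEFAULT_N_GENES,
                       exons_per_gene: tuple[int, int] = DEFAULT_EXONS_PER_GENE,
                       exon_len: tuple[int, int] = DEFAULT_EXON_LEN,
                       intron_len: tuple[int, int] = DEFAULT_INTRON_LEN,
                       seed: int = 0,
                       spacer_len: tuple[int, int] = DEFAULT_SPACER_LEN,
                       ) -> tuple[GenomeSequences, list[ReferenceTranscript]]:
    """Generate an annotated reference genome.

    Genes start with ATG, end with a stop codon, contain no internal
    in-frame stops, and every intron is canonical GT..AG. Intron
    positions fall at arbitrary base offsets, so all three phases occur.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if exons_per_gene[0] < 1 or exons_per_gene[0] > exons_per_gene[1]:
        raise ValueError(f"infeasible exons_per_gene range {exons_per_gene}")
    if exon_len[0] < 9 or exon_len[0] > exon_len[1]:
        raise ValueError(f"infeasible exon_len range {exon_len}")
    if intron_len[0] < 25 or intron_len[0] > intron_len[1] or intron_len[1] > 15000:
        raise ValueError(f"infeasible intron_len range {intron_len} "
                         "(must lie within the allowed intron size bounds)")
    rng = np.random.default_rng(seed)
    payloads = []
    for _ in range(n_genes):
        n_ex = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
        chunks = [int(rng.integers(exon_len[0], exon_len[1] + 1)) for _ in range(n_ex)]
        total = sum(chunks)
        chunks[-1] += (-total) % 3
        n_codons = sum(chunks) // 3
        codons = ["ATG"] + [str(rng.choice(_NON_STOP_CODONS)) for _ in range(n_codons - 2)] \
            + [str(rng.choice(_STOPS))]
        cds = "".join(codons)
        introns = [_random_intron(rng, int(rng.integers(intron_len[0], intron_len[1] + 1)))
                   for _ in range(n_ex - 1)]
        sense, exons = _splice(cds, chunks, introns)
        strand = "+" if rng.random() < 0.5 else "-"
        payloads.append((sense, strand, exons))
    contig, placed = _assemble_contig(rng, payloads, spacer_len)
    genome = GenomeSequences({CONTIG: contig})
    return genome, _build_transcripts(genome, placed)


def _splice(cds: str, chunk_lens: list[int], introns: list[str]):
    """Interleave CDS chunks with intron sequences; returns sense seq + exons."""
    pieces = []
    exons = []
    pos = 0
    cds_off = 0
    for i, clen in enumerate(chunk_lens):
        pieces.append(cds[cds_off:cds_off + clen])
        exons.append((pos, pos + clen))
        pos += clen
        cds_off += clen
        if i < len(introns):
            pieces.append(introns[i])
            pos += len(introns[i])
    return "".join(pieces), exons


def derive_target(genome: GenomeSequences, refs: list[ReferenceTranscript],
                  aa_identity: float = DEFAULT_AA_IDENTITY,
                  intron_shift_prob: float = 0.0,
                  seed: int = 0,
                  spacer_len: tuple[int, int] = DEFAULT_SPACER_LEN,
                  ) -> tuple[GenomeSequences, list[ReferenceTranscript]]:
    """Derive a diverged target genome with known orthologous gene models.

    Codon-level substitutions bring each protein to approximately the
    requested identity (start and stop codons untouched, no stops
    introduced); silent codon changes add nucleotide-level divergence.
    With probability ``intron_shift_prob`` an intron boundary is shifted
    by one codon (frame preserving, canonical motifs maintained); intron
    interiors are regenerated. Returns the target genome and the truth
    annotation for evaluation.
    """
    if not 0 < aa_identity <= 1:
        raise ValueError("aa_identity must be in (0, 1]")
    rng = np.random.default_rng(seed)
    payloads = []
    for ref in refs:
        cds = "".join(genome.fetch(p.seq_id, p.start, p.end, ref.strand)
                      for p in ref.parts)
        codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
        for j in range(1, len(codons) - 1):
            if rng.random() < 1 - aa_identity:
                current = _AA_OF.get(codons[j])
                choices = [aa for aa in _AMINO_ACIDS if aa != current]
                new_aa = choices[int(rng.integers(len(choices)))]
                syn = _CODONS_OF[new_aa]
                codons[j] = syn[int(rng.integers(len(syn)))]
            elif rng.random() < _SYNONYMOUS_PROB:
                syn = _CODONS_OF[_AA_OF[codons[j]]]
                codons[j] = syn[int(rng.integers(len(syn)))]
        if codons[-1] not in _STOPS:
            raise ValueError(f"reference transcript {ref.transcript_id} does not end "
                             "with a stop codon")
        new_cds = "".join(codons)

        offsets = []
        cum = 0
        for p in ref.parts[:-1]:
            cum += len(p)
            offsets.append(cum)
        lengths = [abs(d - a) for d, a in ref.introns]
        new_offsets = []
        lo = 3
        for off in offsets:
            if rng.random() < intron_shift_prob:
                off = off + (3 if rng.random() < 0.5 else -3)
            off = min(max(off, lo), len(new_cds) - 3)
            new_offsets.append(off)
            lo = off + 3
        chunk_lens = np.diff([0] + new_offsets + [len(new_cds)]).tolist()
        introns = [_random_intron(rng, ln) for ln in lengths]
        sense, exons = _splice(new_cds, chunk_lens, introns)
        payloads.append((sense, ref.strand, exons))
    contig, placed = _assemble_contig(rng, payloads, spacer_len)
    target = GenomeSequences({CONTIG: contig})
    return target, _build_transcripts(target, placed, prefix="t")


def simulate_spliced_sam(truth: list[ReferenceTranscript], genome: GenomeSequences,
                         reads_per_intron: int = DEFAULT_READS_PER_INTRON,
                         read_len: int = DEFAULT_READ_LEN,
                         seed: int = 0) -> str:
    """Simulate spliced alignments over a truth annotation as SAM text.

    Every intron of every transcript is spanned by ``reads_per_intron``
    split reads with a correct N CIGAR operation and an XS strand tag,
    and plain exonic reads tile the coding bases so every coding base is
    covered at least once.
    """
    rng = np.random.default_rng(seed)
    lines = ["@HD\tVN:1.6\tSO:coordinate"]
    for name, seq in genome.sequences.items():
        lines.append(f"@SQ\tSN:{name}\tLN:{len(seq)}")
    records = []
    counter = 0

    def emit(seq_id, pos, cigar, seq, strand):
        nonlocal counter
        counter += 1
        records.append((seq_id, pos,
                        f"r{counter}\t0\t{seq_id}\t{pos + 1}\t60\t{cigar}\t*\t0\t0"
                        f"\t{seq}\t*\tXS:A:{strand}"))

    for t in truth:
        contig = genome[t.seq_id]
        parts = sorted(t.parts, key=lambda p: p.start)
        for left, right in zip(parts, parts[1:]):
            s, e = left.end, right.start
            for r in range(reads_per_intron):
                a = min(read_len // 2, len(left))
                jitter = int(rng.integers(0, max(1, min(5, a))))
                a = max(1, a - jitter)
                b = max(1, min(read_len - a, len(right)))
                seq = contig[s - a:s] + contig[e:e + b]
                emit(t.seq_id, s - a, f"{a}M{e - s}N{b}M", seq, t.strand)
        step = max(1, read_len // 2)
        for p in parts:
            for off in range(0, len(p), step):
                start = p.start + off
                length = min(read_len, p.end - start)
                if length < 1:
                    continue
                emit(t.seq_id, start, f"{length}M", contig[start:start + length], t.strand)

    records.sort(key=lambda r: (r[0], r[1]))
    lines.extend(r[2] for r in records)
    return "\n".join(lines) + "\n"


def write_fixture_dir(out_dir: str, n_genes: int = DEFAULT_N_GENES,
                      aa_identity: float = DEFAULT_AA_IDENTITY,
                      intron_shift_prob: float = 0.0,
                      reads_per_intron: int = DEFAULT_READS_PER_INTRON,
                      read_len: int = DEFAULT_READ_LEN, seed: int = 0) -> dict[str, str]:
    """Emit reference FASTA/GFF3, target FASTA, truth GFF3 and SAM files."""
    os.makedirs(out_dir, exist_ok=True)
    genome, refs = generate_reference(n_genes=n_genes, seed=seed)
    target, truth = derive_target(genome, refs, aa_identity=aa_identity,
                                  intron_shift_prob=intron_shift_prob, seed=seed + 1)
    sam = simulate_spliced_sam(truth, target, reads_per_intron=reads_per_intron,
                               read_len=read_len, seed=seed + 2)
    paths = {
        "reference_fasta": os.path.join(out_dir, "reference.fasta"),
        "reference_gff": os.path.join(out_dir, "reference.gff3"),
        "target_fasta": os.path.join(out_dir, "target.fasta"),
        "truth_gff": os.path.join(out_dir, "truth.gff3"),
        "rnaseq_sam": os.path.join(out_dir, "rnaseq.sam"),
    }
    write_fasta(genome, paths["reference_fasta"])
    write_reference_gff3(refs, paths["reference_gff"])
    write_fasta(target, paths["target_fasta"])
    write_reference_gff3(truth, paths["truth_gff"])
    with open(paths["rnaseq_sam"], "w") as fh:
        fh.write(sam)
    return paths
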