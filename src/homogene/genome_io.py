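"""Genome and annotation I/O.

Reads FASTA genomes and GFF3 annotations, decomposes each annotated mRNA
into its ordered coding parts (with phases, per-part peptides and intron
positions) and writes predicted gene models back to GFF3.

Coordinate conventions: everything internal is 0-based half-open;
GFF3 input/output converts to and from the 1-based inclusive convention.
"""

from __future__ import annotations

import logging
import os
from bisect import bisect_right
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

STOP_CODONS = {"TAA", "TAG", "TGA"}
_DNA_ALPHABET = set("ACGTN")


def reverse_complement(dna: str) -> str:
    return str(Seq(dna).reverse_complement())


def translate(dna: str, phase: int = 0) -> str:
    """Standard-code translation of ``dna`` starting at offset ``phase``.

    A trailing incomplete codon is ignored and a trailing stop codon is
    dropped; internal stops are rendered as ``*``.
    """
    if phase not in (0, 1, 2):
        raise ValueError(f"phase must be 0, 1 or 2, got {phase!r}")
    trimmed = dna[phase:]
    trimmed = trimmed[: len(trimmed) // 3 * 3]
    protein = str(Seq(trimmed).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    return protein


@dataclass
class GenomeSequences:
    """A set of named DNA sequences (uppercase, alphabet ACGTN)."""

    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        upper = {}
        for name, seq in self.sequences.items():
            seq = seq.upper()
            bad = set(seq) - _DNA_ALPHABET
            if bad:
                raise ValueError(f"sequence {name!r} contains non-DNA symbols {sorted(bad)}")
            upper[name] = seq
        self.sequences = upper

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self.sequences

    def __getitem__(self, seq_id: str) -> str:
        return self.sequences[seq_id]

    def length(self, seq_id: str) -> int:
        return len(self.sequences[seq_id])

    def fetch(self, seq_id: str, start: int, end: int, strand: str = "+") -> str:
        """Sub-sequence on the requested strand (0-based half-open)."""
        seq = self.sequences[seq_id][max(start, 0):end]
        return reverse_complement(seq) if strand == "-" else seq


@dataclass(frozen=True)
class CodingPart:
    """One coding exon segment: 0-based half-open genomic interval.

    ``phase`` is the number of bases at the 5' end (in translation order)
    belonging to a codon begun in the previous part, as in GFF3 column 8.
    """

    seq_id: str
    start: int
    end: int
    strand: str
    phase: int = 0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty or inverted part [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.phase not in (0, 1, 2):
            raise ValueError(f"phase must be 0, 1 or 2, got {self.phase!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ReferenceTranscript:
    """A reference gene model decomposed into ordered coding parts.

    ``parts`` are in translation order (reverse genomic order on the -
    strand), ``protein`` is the translation of the joined coding sequence
    (final stop excluded), ``part_peptides`` holds one peptide per part
    with split codons assigned to the part containing at least two of the
    codon's bases, and ``introns`` lists (donor_pos, acceptor_pos) genomic
    boundary coordinates between consecutive parts.
    """

    transcript_id: str
    gene_id: str
    parts: list[CodingPart]
    protein: str
    part_peptides: list[str]
    introns: list[tuple[int, int]]
    complete: bool = True

    @property
    def seq_id(self) -> str:
        return self.parts[0].seq_id

    @property
    def strand(self) -> str:
        return self.parts[0].strand

    def coding_length(self) -> int:
        return sum(len(p) for p in self.parts)

    def span(self) -> tuple[int, int]:
        return min(p.start for p in self.parts), max(p.end for p in self.parts)

    def intron_intervals(self) -> list[tuple[int, int]]:
        """Genomic 0-based half-open intervals of the introns."""
        out = []
        for donor, acceptor in self.introns:
            out.append((donor, acceptor) if self.strand == "+" else (acceptor, donor))
        return out


def compute_phases(part_lengths: list[int], first_phase: int = 0) -> list[int]:
    """GFF3 phases along translation order from part lengths."""
    phases = [first_phase]
    cum = -first_phase
    for length in part_lengths[:-1]:
        cum += length
        phases.append((-cum) % 3)
    return phases


def _part_peptides(parts: list[CodingPart], protein: str, first_phase: int) -> list[str]:
    """Assign each amino acid to the part holding >=2 bases of its codon."""
    cum_starts = []
    total = 0
    for p in parts:
        cum_starts.append(total)
        total += len(p)
    peptides = [""] * len(parts)
    for aa_index, aa in enumerate(protein):
        counts = {}
        for b in range(3):
            offset = first_phase + 3 * aa_index + b
            idx = bisect_right(cum_starts, offset) - 1
            counts[idx] = counts.get(idx, 0) + 1
        best = max(counts, key=lambda i: (counts[i], -i))
        peptides[best] += aa
    return peptides


def build_transcript(transcript_id: str, gene_id: str, parts: list[CodingPart],
                     genome: GenomeSequences, phases: list[int] | None = None) -> ReferenceTranscript | None:
    """Assemble a ReferenceTranscript from genomically sorted-by-start parts.

    Returns None (with a warning) when the coding sequence contains an
    internal stop codon.
    """
    strand = parts[0].strand
    ordered = sorted(parts, key=lambda p: p.start, reverse=(strand == "-"))
    if phases is None:
        first = ordered[0].phase
        phases = compute_phases([len(p) for p in ordered], first)
    ordered = [CodingPart(p.seq_id, p.start, p.end, p.strand, ph)
               for p, ph in zip(ordered, phases)]
    cds = "".join(genome.fetch(p.seq_id, p.start, p.end, strand) for p in ordered)
    first_phase = ordered[0].phase
    protein = translate(cds, first_phase)
    if "*" in protein:
        logger.warning("transcript %s has an internal stop codon; skipped", transcript_id)
        return None
    introns = []
    for u, v in zip(ordered, ordered[1:]):
        if strand == "+":
            introns.append((u.end, v.start))
        else:
            introns.append((u.start, v.end))
    trimmed = cds[first_phase:]
    complete = (first_phase == 0 and cds.startswith("ATG")
                and len(trimmed) % 3 == 0 and trimmed[-3:] in STOP_CODONS)
    peptides = _part_peptides(ordered, protein, first_phase)
    return ReferenceTranscript(transcript_id, gene_id, ordered, protein,
                               peptides, introns, complete=complete)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str) -> GenomeSequences:
    records = {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}
    return GenomeSequences(records)


def write_fasta(genome: GenomeSequences, path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 reading

def _open_gff_db(annotation: str):
    from_string = "\n" in annotation or annotation.lstrip().startswith("#")
    if not from_string and not os.path.exists(annotation):
        raise FileNotFoundError(annotation)
    if not from_string:
        with open(annotation) as fh:
            annotation = fh.read()
    if not any(line.strip() and not line.startswith("#")
               for line in annotation.splitlines()):
        return None
    return gffutils.create_db(annotation, dbfn=":memory:", from_string=True,
                              merge_strategy="create_unique", keep_order=True)


def load_reference(genome: GenomeSequences, annotation: str) -> list[ReferenceTranscript]:
    """Decompose a GFF3 annotation into reference transcripts.

    ``annotation`` may be a path or GFF3 content. One transcript is built
    per parent (mRNA) with at least one CDS feature; transcripts whose
    coding sequence contains an internal stop are skipped with a warning.
    """
    db = _open_gff_db(annotation)
    if db is None:
        return []
    by_parent: dict[str, list] = {}
    for cds in db.features_of_type("CDS"):
        if cds.seqid not in genome:
            raise ValueError(f"CDS references unknown sequence id {cds.seqid!r}")
        parents = cds.attributes.get("Parent", [cds.id or "unknown"])
        for parent in parents:
            by_parent.setdefault(parent, []).append(cds)

    transcripts = []
    for tid in by_parent:
        features = by_parent[tid]
        strand = features[0].strand
        gene_id = tid
        try:
            mrna = db[tid]
            gene_id = mrna.attributes.get("Parent", [tid])[0]
        except gffutils.FeatureNotFoundError:
            pass
        raw = sorted(features, key=lambda f: f.start, reverse=(strand == "-"))
        phases = []
        for f in raw:
            phases.append(int(f.frame) if f.frame in ("0", "1", "2") else None)
        if any(ph is None for ph in phases):
            phases = compute_phases([f.end - f.start + 1 for f in raw],
                                    phases[0] if phases[0] is not None else 0)
        parts = [CodingPart(f.seqid, f.start - 1, f.end, strand, ph)
                 for f, ph in zip(raw, phases)]
        t = build_transcript(tid, gene_id, parts, genome, phases=phases)
        if t is not None:
            transcripts.append(t)
    transcripts.sort(key=lambda t: (t.seq_id, t.span()[0], t.transcript_id))
    return transcripts


# ---------------------------------------------------------------------------
# GFF3 writing

_ATTRIBUTE_ORDER = ["tie", "tpc", "tae", "tde", "minCov", "avgCov",
                    "minSplitReads", "pAA", "iAA", "evidence", "alternative"]


def _format_value(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        return f"{value:.10g}"
    if isinstance(value, (list, tuple)):
        return ",".join(str(v) for v in value)
    return str(value)


def _check_parts(parts: list[CodingPart]) -> None:
    ordered = sorted(parts, key=lambda p: p.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise ValueError(f"overlapping coding parts [{a.start},{a.end}) and [{b.start},{b.end})")


def write_reference_gff3(transcripts: list[ReferenceTranscript], path: str) -> None:
    """Write reference transcripts as gene/mRNA/CDS GFF3."""
    lines = ["##gff-version 3"]
    by_gene: dict[str, list[ReferenceTranscript]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    for gene_id, members in by_gene.items():
        start = min(t.span()[0] for t in members)
        end = max(t.span()[1] for t in members)
        first = members[0]
        lines.append("\t".join([first.seq_id, "homogene", "gene", str(start + 1), str(end),
                                ".", first.strand, ".", f"ID={gene_id}"]))
        for t in members:
            _check_parts(t.parts)
            s, e = t.span()
            lines.append("\t".join([t.seq_id, "homogene", "mRNA", str(s + 1), str(e),
                                    ".", t.strand, ".", f"ID={t.transcript_id};Parent={gene_id}"]))
            for p in t.parts:
                lines.append("\t".join([p.seq_id, "homogene", "CDS", str(p.start + 1), str(p.end),
                                        ".", p.strand, str(p.phase),
                                        f"ID=cds_{t.transcript_id};Parent={t.transcript_id}"]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_predictions_gff3(predictions, path: str) -> None:
    """Write predicted transcripts (gene/mRNA/CDS) with evidence attributes.

    Undefined statistics (e.g. tie of a single-coding-exon model) are
    written as ``NA``. Raises on overlapping parts within one transcript.
    """
    lines = ["##gff-version 3"]
    by_gene: dict[str, list] = {}
    for p in predictions:
        gene = p.attributes.get("gene") or f"gene_of_{p.prediction_id}"
        by_gene.setdefault(gene, []).append(p)
    for gene_id, members in by_gene.items():
        start = min(p.span()[0] for p in members)
        end = max(p.span()[1] for p in members)
        first = members[0]
        lines.append("\t".join([first.seq_id, "homogene", "gene", str(start + 1), str(end),
                                ".", first.strand, ".", f"ID={gene_id}"]))
        for p in members:
            _check_parts(p.parts)
            s, e = p.span()
            attrs = [f"ID={p.prediction_id}", f"Parent={gene_id}",
                     f"ref_transcript={p.reference_transcript_id}",
                     f"complete={'true' if p.complete else 'false'}"]
            for key in _ATTRIBUTE_ORDER:
                if key in p.attributes:
                    attrs.append(f"{key}={_format_value(p.attributes[key])}")
            score = _format_value(float(p.score)) if p.score is not None else "."
            lines.append("\t".join([p.seq_id, "homogene", "mRNA", str(s + 1), str(e),
                                    score, p.strand, ".", ";".join(attrs)]))
            for part in p.parts:
                lines.append("\t".join([part.seq_id, "homogene", "CDS",
                                        str(part.start + 1), str(part.end), ".",
                                        part.strand, str(part.phase),
                                        f"ID=cds_{p.prediction_id};Parent={p.prediction_id}"]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_predictions_gff3(annotation: str):
    """Read a predictions GFF3 written by :func:`write_predictions_gff3`."""
    from .model_builder import PredictedTranscript

    db = _open_gff_db(annotation)
    if db is None:
        return []
    preds = []
    for mrna in db.features_of_type("mRNA"):
        pid = mrna.attributes["ID"][0]
        cds = sorted(db.children(mrna, featuretype="CDS"), key=lambda f: f.start)
        if not cds:
            continue
        strand = mrna.strand
        parts = [CodingPart(f.seqid, f.start - 1, f.end, strand,
                            int(f.frame) if f.frame in ("0", "1", "2") else 0)
                 for f in cds]
        if strand == "-":
            parts = parts[::-1]
        attributes = {}
        for key in _ATTRIBUTE_ORDER + ["gene"]:
            if key in mrna.attributes:
                raw = mrna.attributes[key][0] if len(mrna.attributes[key]) == 1 \
                    else list(mrna.attributes[key])
                attributes[key] = _parse_value(key, raw)
        if "Parent" in mrna.attributes:
            attributes["gene"] = mrna.attributes["Parent"][0]
        ref_id = mrna.attributes.get("ref_transcript", [pid])[0]
        complete = mrna.attributes.get("complete", ["true"])[0] == "true"
        score = None if mrna.score in (".", "", None) else float(mrna.score)
        preds.append(PredictedTranscript(
            prediction_id=pid, reference_transcript_id=ref_id,
            parts=parts, protein="", score=score if score is not None else 0.0,
            complete=complete, attributes=attributes))
    preds.sort(key=lambda p: (p.seq_id, p.span()[0], p.prediction_id))
    return preds


def _parse_value(key: str, raw):
    if isinstance(raw, list):
        return raw
    if raw == "NA":
        return None
    if key in ("alternative",):
        return raw.split(",") if raw else []
    if key == "evidence":
        return int(raw)
    try:
        f = float(raw)
        return int(f) if f.is_integer() and key in ("minCov", "minSplitReads") else f
    except ValueError:
        return raw
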