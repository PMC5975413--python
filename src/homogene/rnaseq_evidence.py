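"""Extraction of RNA-seq evidence (the ERE stage).

Mapped spliced reads carry introns as N operations in their CIGAR strings;
each N operation within the allowed size range contributes one split-read
observation of an intron. Optionally a per-base read-coverage track is
accumulated from the aligned (M/=/X) segments. Introns passing a
split-read threshold define donor and acceptor splice-site candidates;
where no experimental evidence exists in a region, conserved dinucleotides
(GT/GC for donors, AG for acceptors) are used as the fallback.
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import dataclass, field

import numpy as np
import pysam

from .genome_io import GenomeSequences

logger = logging.getLogger(__name__)

DEFAULT_MIN_INTRON = 25
DEFAULT_MAX_INTRON = 15000

UNKNOWN = "unknown"


@dataclass(frozen=True)
class IntronEvidence:
    """An intron observed in split reads: 0-based half-open genomic span."""

    seq_id: str
    start: int
    end: int
    strand: str  # '+', '-' or 'unknown'
    split_reads: int = 1

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class CoverageTrack:
    """Per-base counts of aligned read bases, one array per sequence."""

    counts: dict[str, np.ndarray] = field(default_factory=dict)

    def array(self, seq_id: str) -> np.ndarray | None:
        return self.counts.get(seq_id)

    def slice(self, seq_id: str, start: int, end: int) -> np.ndarray:
        arr = self.counts.get(seq_id)
        if arr is None:
            return np.zeros(end - start, dtype=np.int64)
        out = np.zeros(end - start, dtype=np.int64)
        lo, hi = max(start, 0), min(end, len(arr))
        if hi > lo:
            out[lo - start:hi - start] = arr[lo:hi]
        return out

    def total(self) -> int:
        return int(sum(arr.sum() for arr in self.counts.values()))


@dataclass(frozen=True)
class SpliceSiteCandidate:
    """A candidate exon/intron boundary.

    ``pos`` is the genomic coordinate of the boundary in half-open terms:
    for a donor on the + strand the intron starts at ``pos`` (the exon ends
    there); for an acceptor on the + strand the next exon starts at ``pos``.
    On the - strand donor and acceptor swap intron ends.
    """

    seq_id: str
    pos: int
    kind: str            # 'donor' or 'acceptor'
    strand: str
    source: str          # 'evidence' or 'dinucleotide'
    split_reads: int = 0


def _ensure_sam_header(path: str) -> str:
    """pysam needs @SQ lines to resolve reference names; synthesize if absent."""
    with open(path) as fh:
        text = fh.read()
    if "@SQ" in text:
        return path
    max_end: dict[str, int] = {}
    for line in text.splitlines():
        if not line or line.startswith("@"):
            continue
        fields = line.split("\t")
        if len(fields) < 11 or fields[2] == "*":
            continue
        try:
            pos = int(fields[3])
        except ValueError:
            continue
        max_end[fields[2]] = max(max_end.get(fields[2], 0), pos + 10_000_000)
    header = "".join(f"@SQ\tSN:{name}\tLN:{ln}\n" for name, ln in max_end.items())
    tmp = tempfile.NamedTemporaryFile("w", suffix=".sam", delete=False)
    tmp.write(header + text)
    tmp.close()
    return tmp.name

_MATCH_OPS = {0, 7, 8}      # M, =, X advance reference and count as coverage
_REF_SKIP = 3               # N
_DELETION = 2               # D advances reference without coverage


def extract_evidence(sam: str,
                     min_intron: int = DEFAULT_MIN_INTRON,
                     max_intron: int = DEFAULT_MAX_INTRON,
                     with_coverage: bool = False,
                     genome: GenomeSequences | None = None,
                     ) -> tuple[list[IntronEvidence], CoverageTrack | None]:
    """Extract introns (and optionally coverage) from a SAM file or text.

    Each N CIGAR operation whose span lies within [min_intron, max_intron]
    contributes one intron occurrence; identical occurrences are merged
    with summed split-read counts. The intron strand comes from the
    per-read XS tag when present, otherwise from boundary dinucleotides if
    a genome is supplied, otherwise it is 'unknown'.
    """
    path = sam
    cleanup = None
    if "\n" in sam or not os.path.exists(sam):
        tmp = tempfile.NamedTemporaryFile("w", suffix=".sam", delete=False)
        tmp.write(sam)
        tmp.close()
        path = cleanup = tmp.name
    path = _ensure_sam_header(path)

    counts: dict[tuple[str, int, int, str], int] = {}
    coverage: dict[str, np.ndarray] = {}
    try:
        with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
            lengths = dict(zip(fh.references, fh.lengths))
            for read in fh:
                if read.is_unmapped or read.cigartuples is None:
                    continue
                seq_id = read.reference_name
                if with_coverage and seq_id not in coverage:
                    coverage[seq_id] = np.zeros(lengths.get(seq_id, 0), dtype=np.int64)
                pos = read.reference_start
                strand_tag = None
                if read.has_tag("XS"):
                    tag = read.get_tag("XS")
                    if tag in ("+", "-"):
                        strand_tag = tag
                for op, length in read.cigartuples:
                    if op in _MATCH_OPS:
                        if with_coverage:
                            arr = coverage[seq_id]
                            if pos + length > len(arr):
                                arr = np.concatenate(
                                    [arr, np.zeros(pos + length - len(arr), dtype=np.int64)])
                                coverage[seq_id] = arr
                            arr[pos:pos + length] += 1
                        pos += length
                    elif op == _REF_SKIP:
                        if min_intron <= length <= max_intron:
                            strand = strand_tag or _infer_strand(genome, seq_id, pos, pos + length)
                            key = (seq_id, pos, pos + length, strand)
                            counts[key] = counts.get(key, 0) + 1
                        pos += length
                    elif op == _DELETION:
                        pos += length
                    # insertions / clips do not advance the reference
    finally:
        if cleanup is not None:
            os.unlink(cleanup)

    introns = [IntronEvidence(s, a, b, strand, n)
               for (s, a, b, strand), n in sorted(counts.items())]
    track = CoverageTrack(coverage) if with_coverage else None
    return introns, track


def _infer_strand(genome: GenomeSequences | None, seq_id: str, start: int, end: int) -> str:
    if genome is None or seq_id not in genome:
        return UNKNOWN
    seq = genome[seq_id]
    donor, acceptor = seq[start:start + 2], seq[end - 2:end]
    if donor in ("GT", "GC") and acceptor == "AG":
        return "+"
    if donor == "CT" and acceptor in ("AC", "GC"):
        return "-"
    return UNKNOWN


def filter_introns(introns: list[IntronEvidence], min_split_reads: int = 1) -> list[IntronEvidence]:
    """Keep introns supported by at least ``min_split_reads`` split reads."""
    if min_split_reads < 1:
        raise ValueError("min_split_reads must be >= 1")
    return [i for i in introns if i.split_reads >= min_split_reads]


def _strand_compatible(intron_strand: str, strand: str) -> bool:
    return intron_strand == UNKNOWN or intron_strand == strand


def splice_candidates(region: tuple[str, int, int], strand: str,
                      introns: list[IntronEvidence], genome: GenomeSequences,
                      kind: str) -> list[SpliceSiteCandidate]:
    """Splice-site candidates of one kind within a genomic region.

    Experimental intron boundaries take precedence: if any evidence
    boundary of the requested kind lies in the region, only evidence
    candidates are returned; otherwise the region is scanned for the
    conserved dinucleotides (GT/GC donors, AG acceptors) on the coding
    strand.
    """
    seq_id, start, end = region
    if kind not in ("donor", "acceptor"):
        raise ValueError(f"kind must be 'donor' or 'acceptor', got {kind!r}")
    evidence = []
    for intron in introns:
        if intron.seq_id != seq_id or not _strand_compatible(intron.strand, strand):
            continue
        if (kind == "donor") == (strand == "+"):
            pos = intron.start
        else:
            pos = intron.end
        if start <= pos < end:
            evidence.append(SpliceSiteCandidate(seq_id, pos, kind, strand,
                                                "evidence", intron.split_reads))
    if evidence:
        evidence.sort(key=lambda c: c.pos)
        return evidence

    seq = genome[seq_id]
    out = []
    if strand == "+":
        motifs = ("GT", "GC") if kind == "donor" else ("AG",)
        for p in range(max(start, 0), min(end, len(seq)) - 1):
            if seq[p:p + 2] in motifs:
                # donor: intron starts at the G; acceptor: exon starts after the AG
                out.append(SpliceSiteCandidate(seq_id, p if kind == "donor" else p + 2,
                                               kind, strand, "dinucleotide"))
    else:
        # reverse-strand motifs on the forward sequence
        motifs = ("AC", "GC") if kind == "donor" else ("CT",)
        for p in range(max(start, 0), min(end, len(seq)) - 1):
            if seq[p:p + 2] in motifs:
                out.append(SpliceSiteCandidate(seq_id, p + 2 if kind == "donor" else p,
                                               kind, strand, "dinucleotide"))
    return out


# ---------------------------------------------------------------------------
# BED / bedGraph I/O

def write_introns_bed(introns: list[IntronEvidence], path: str) -> None:
    with open(path, "w") as fh:
        for i, intron in enumerate(introns):
            strand = intron.strand if intron.strand in ("+", "-") else "."
            fh.write(f"{intron.seq_id}\t{intron.start}\t{intron.end}"
                     f"\tintron_{i}\t{intron.split_reads}\t{strand}\n")


def read_introns_bed(path: str) -> list[IntronEvidence]:
    introns = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else UNKNOWN
            introns.append(IntronEvidence(fields[0], int(fields[1]), int(fields[2]),
                                          strand, int(float(fields[4]))))
    return introns


def write_coverage_bedgraph(track: CoverageTrack, path: str) -> None:
    with open(path, "w") as fh:
        for seq_id, arr in track.counts.items():
            if len(arr) == 0:
                continue
            breaks = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], breaks])
            ends = np.concatenate([breaks, [len(arr)]])
            for s, e in zip(starts, ends):
                v = int(arr[s])
                if v:
                    fh.write(f"{seq_id}\t{s}\t{e}\t{v}\n")


def read_coverage_bedgraph(path: str, lengths: dict[str, int] | None = None) -> CoverageTrack:
    rows: dict[str, list[tuple[int, int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            seq_id, s, e, v = line.split("\t")
            rows.setdefault(seq_id, []).append((int(s), int(e), int(v)))
    counts = {}
    for seq_id, segs in rows.items():
        size = max(e for _, e, _ in segs)
        if lengths and seq_id in lengths:
            size = max(size, lengths[seq_id])
        arr = np.zeros(size, dtype=np.int64)
        for s, e, v in segs:
            arr[s:e] = v
        counts[seq_id] = arr
    return CoverageTrack(counts)
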