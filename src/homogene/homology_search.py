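"""Translated homology search: locate reference coding parts on a target.

Each reference part peptide is aligned (Smith-Waterman, affine gaps,
BLOSUM62) against all six reading frames of every target sequence; hits
above a fraction of the peptide's self-score are reported with their
genomic coordinates. Externally computed hits in the common 12-column
tabular format can be imported instead for large genomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from . import align as _align
from .genome_io import GenomeSequences, ReferenceTranscript, reverse_complement, translate

logger = logging.getLogger(__name__)

MIN_INDEPENDENT_PEPTIDE = 8
DEFAULT_MIN_SCORE_FRACTION = 0.3
_MAX_HITS_PER_FRAME = 8


@dataclass(frozen=True)
class ExonHit:
    """A local translated-alignment match of one reference coding part."""

    transcript_id: str
    part_index: int
    seq_id: str
    start: int          # 0-based half-open genomic interval on the + strand
    end: int
    strand: str
    frame: int          # codon frame of the hit start on its sense strand
    score: float
    query_cover: float  # fraction of the part peptide aligned

    def __post_init__(self) -> None:
        if not 0.0 <= self.query_cover <= 1.0 + 1e-9:
            raise ValueError("query_cover outside [0, 1]")


def align_local(query: str, subject: str,
                matrix_name: str = _align.DEFAULT_MATRIX,
                gap_open: int = _align.DEFAULT_GAP_OPEN,
                gap_extend: int = _align.DEFAULT_GAP_EXTEND,
                ) -> tuple[float, tuple[tuple[int, int], tuple[int, int]], list]:
    """Smith-Waterman local alignment of two peptides.

    Returns ``(score, ((q_start, q_end), (s_start, s_end)), columns)``
    where columns is a list of ``(query_index, subject_index)`` pairs with
    ``None`` marking a gap. Empty alignments score 0.
    """
    _align.check_protein(query, matrix_name)
    _align.check_protein(subject, matrix_name)
    if not query or not subject:
        return 0.0, ((0, 0), (0, 0)), []
    aligner = _align.local_aligner(matrix_name, gap_open, gap_extend)
    score = aligner.score(query, subject)
    if score <= 0:
        return 0.0, ((0, 0), (0, 0)), []
    aln = aligner.align(query, subject)[0]
    blocks = aln.aligned
    q_start, q_end = int(blocks[0][0][0]), int(blocks[0][-1][1])
    s_start, s_end = int(blocks[1][0][0]), int(blocks[1][-1][1])
    columns = []
    prev_q, prev_s = None, None
    for (qa, qb), (sa, sb) in zip(blocks[0], blocks[1]):
        if prev_q is not None:
            columns.extend((qi, None) for qi in range(prev_q, qa))
            columns.extend((None, si) for si in range(prev_s, sa))
        columns.extend(zip(range(qa, qb), range(sa, sb)))
        prev_q, prev_s = qb, sb
    return float(score), ((q_start, q_end), (s_start, s_end)), columns


def _frame_peptides(seq: str):
    """Yield (strand, frame, peptide) for all six reading frames."""
    rc = reverse_complement(seq)
    for frame in range(3):
        yield "+", frame, translate(seq, frame)
        yield "-", frame, translate(rc, frame)


def _queries_for(ref: ReferenceTranscript):
    """Part peptides to search; short peptides are merged with a neighbor."""
    queries = []
    i = 0
    peps = ref.part_peptides
    while i < len(peps):
        pep = peps[i]
        anchor = i
        covered = [i]
        while len(pep) < MIN_INDEPENDENT_PEPTIDE and i + 1 < len(peps):
            i += 1
            pep = pep + peps[i]
            covered.append(i)
            anchor = i if len(peps[i]) > len(peps[anchor]) else anchor
        if len(pep) < MIN_INDEPENDENT_PEPTIDE and queries:
            # trailing short part: fold into the previous query
            prev_anchor, prev_pep, prev_covered = queries.pop()
            logger.info("part %d of %s too short for independent search; merged",
                        covered[0], ref.transcript_id)
            queries.append((prev_anchor, prev_pep + pep, prev_covered + covered))
            i += 1
            continue
        if len(covered) > 1:
            logger.info("parts %s of %s searched jointly (short peptide)",
                        covered, ref.transcript_id)
        queries.append((anchor, pep, covered))
        i += 1
    return queries


def find_exon_hits(ref: ReferenceTranscript, target: GenomeSequences,
                   min_score_fraction: float = DEFAULT_MIN_SCORE_FRACTION,
                   matrix_name: str = _align.DEFAULT_MATRIX,
                   gap_open: int = _align.DEFAULT_GAP_OPEN,
                   gap_extend: int = _align.DEFAULT_GAP_EXTEND) -> list[ExonHit]:
    """Six-frame translated search of every part peptide against a target."""
    if not target.sequences:
        raise ValueError("target genome is empty")
    aligner = _align.local_aligner(matrix_name, gap_open, gap_extend)
    hits: list[ExonHit] = []
    frames = {}
    for seq_id, seq in target.sequences.items():
        frames[seq_id] = list(_frame_peptides(seq))
    for part_index, peptide, _covered in _queries_for(ref):
        if not peptide:
            continue
        threshold = max(min_score_fraction * _align.self_score(peptide, matrix_name), 1.0)
        for seq_id, seq in target.sequences.items():
            length = len(seq)
            for strand, frame, subject_pep in frames[seq_id]:
                subject = subject_pep
                for _ in range(_MAX_HITS_PER_FRAME):
                    score = aligner.score(peptide, subject)
                    if score < threshold:
                        break
                    aln = aligner.align(peptide, subject)[0]
                    blocks = aln.aligned
                    qa, qb = int(blocks[0][0][0]), int(blocks[0][-1][1])
                    sa, sb = int(blocks[1][0][0]), int(blocks[1][-1][1])
                    if strand == "+":
                        g_start, g_end = frame + 3 * sa, frame + 3 * sb
                    else:
                        g_start, g_end = length - (frame + 3 * sb), length - (frame + 3 * sa)
                    hits.append(ExonHit(ref.transcript_id, part_index, seq_id,
                                        g_start, g_end, strand, g_start % 3 if strand == "+"
                                        else (length - g_end) % 3,
                                        float(score), (qb - qa) / len(peptide)))
                    subject = subject[:sa] + "X" * (sb - sa) + subject[sb:]
    hits.sort(key=lambda h: (-h.score, h.seq_id, h.start))
    return hits


def read_tabular_hits(path: str, refs: list[ReferenceTranscript]) -> list[ExonHit]:
    """Import externally computed hits in 12-column tabular format.

    Query ids must encode the transcript and 0-based part index as
    ``<transcript_id>|<part_index>``. Subject coordinates are 1-based
    inclusive; ``sstart > send`` marks a minus-strand hit.
    """
    peptide_len = {}
    for ref in refs:
        for i, pep in enumerate(ref.part_peptides):
            peptide_len[(ref.transcript_id, i)] = len(pep)
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 12:
                raise ValueError(f"line {lineno}: expected 12 tab-separated columns, "
                                 f"got {len(fields)}")
            query_id, subject_id = fields[0], fields[1]
            if "|" not in query_id:
                raise ValueError(f"line {lineno}: query id {query_id!r} does not encode "
                                 "'<transcript_id>|<part_index>'")
            tid, _, idx = query_id.rpartition("|")
            part_index = int(idx)
            qstart, qend = int(fields[6]), int(fields[7])
            sstart, send = int(fields[8]), int(fields[9])
            bitscore = float(fields[11])
            if sstart <= send:
                start, end, strand = sstart - 1, send, "+"
            else:
                start, end, strand = send - 1, sstart, "-"
            plen = peptide_len.get((tid, part_index), 0)
            cover = min((qend - qstart + 1) / plen, 1.0) if plen else 1.0
            frame = start % 3 if strand == "+" else 0
            hits.append(ExonHit(tid, part_index, subject_id, start, end, strand,
                                frame, bitscore, cover))
    hits.sort(key=lambda h: (-h.score, h.seq_id, h.start))
    return hits
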