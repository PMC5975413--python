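"""Per-prediction evidence statistics.

Annotates predicted (or annotated) transcripts with the RNA-seq support
statistics: tie (fraction of introns exactly matched by split-read
introns; NA for single-coding-exon models), tpc (fraction of coding bases
covered), tae/tde (fractions of acceptor/donor sites with evidence),
minCov/avgCov (minimum and mean coverage over coding bases),
minSplitReads (minimum split-read count over the introns, NA unless all
introns are matched), and the protein-alignment statistics pAA/iAA.
"""

from __future__ import annotations

import numpy as np

from . import align as _align
from .rnaseq_evidence import UNKNOWN, CoverageTrack, IntronEvidence


def _evidence_index(introns: list[IntronEvidence], seq_id: str, strand: str):
    """Split-read counts for introns on one sequence, strand-compatible."""
    exact: dict[tuple[int, int], int] = {}
    donors: set[int] = set()
    acceptors: set[int] = set()
    for intron in introns:
        if intron.seq_id != seq_id:
            continue
        if intron.strand not in (strand, UNKNOWN):
            continue
        key = (intron.start, intron.end)
        exact[key] = exact.get(key, 0) + intron.split_reads
        if strand == "+":
            donors.add(intron.start)
            acceptors.add(intron.end)
        else:
            donors.add(intron.end)
            acceptors.add(intron.start)
    return exact, donors, acceptors


def annotate(prediction, introns: list[IntronEvidence],
             coverage: CoverageTrack | None = None):
    """Fill a prediction's evidence attributes in place and return it.

    An intron counts as supported only when both boundaries match an
    evidence intron exactly; introns of unknown strand support either
    strand. Coverage statistics are NA when no coverage track is given.
    """
    if not prediction.parts:
        raise ValueError("prediction has no coding parts")
    seq_id, strand = prediction.seq_id, prediction.strand
    exact, donor_set, acceptor_set = _evidence_index(introns, seq_id, strand)

    intervals = prediction.intron_intervals()
    attrs = prediction.attributes
    if not intervals:
        attrs["tie"] = None
        attrs["tae"] = None
        attrs["tde"] = None
        attrs["minSplitReads"] = None
    else:
        matched = [exact.get(iv) for iv in intervals]
        attrs["tie"] = sum(m is not None for m in matched) / len(intervals)
        if strand == "+":
            donor_pos = [iv[0] for iv in intervals]
            acceptor_pos = [iv[1] for iv in intervals]
        else:
            donor_pos = [iv[1] for iv in intervals]
            acceptor_pos = [iv[0] for iv in intervals]
        attrs["tde"] = sum(p in donor_set for p in donor_pos) / len(intervals)
        attrs["tae"] = sum(p in acceptor_set for p in acceptor_pos) / len(intervals)
        attrs["minSplitReads"] = (min(matched) if all(m is not None for m in matched)
                                  else None)

    if coverage is None:
        attrs["tpc"] = None
        attrs["minCov"] = None
        attrs["avgCov"] = None
    else:
        depths = np.concatenate([coverage.slice(seq_id, p.start, p.end)
                                 for p in prediction.parts])
        attrs["tpc"] = float((depths > 0).mean())
        attrs["minCov"] = int(depths.min())
        attrs["avgCov"] = float(depths.mean())
    return prediction


def alignment_stats(predicted_protein: str, reference_protein: str,
                    matrix_name: str = _align.DEFAULT_MATRIX,
                    gap_open: int = _align.DEFAULT_GAP_OPEN,
                    gap_extend: int = _align.DEFAULT_GAP_EXTEND) -> tuple[float, float]:
    """pAA and iAA: percentages of positive-scoring and identical columns.

    Computed over all columns (gap columns included in the denominator) of
    the global alignment of the two proteins. Identical columns always
    score positive, so pAA >= iAA.
    """
    if not predicted_protein or not reference_protein:
        raise ValueError("both proteins must be non-empty")
    matrix = _align.load_matrix(matrix_name)
    aligner = _align.global_aligner(matrix_name, gap_open, gap_extend)
    aln = aligner.align(predicted_protein, reference_protein)[0]
    a_row, b_row = str(aln[0]), str(aln[1])
    columns = len(a_row)
    identical = 0
    positive = 0
    for x, y in zip(a_row, b_row):
        if x == "-" or y == "-":
            continue
        if x == y:
            identical += 1
        if matrix[x, y] > 0:
            positive += 1
    return 100.0 * positive / columns, 100.0 * identical / columns


def annotate_all(predictions, introns, coverage=None, refs=None):
    """Annotate a list of predictions; optionally add pAA/iAA versus refs.

    ``refs`` maps reference transcript ids to their proteins (or is a list
    of reference transcripts).
    """
    proteins = {}
    if refs is not None:
        if isinstance(refs, dict):
            proteins = refs
        else:
            proteins = {r.transcript_id: r.protein for r in refs}
    for p in predictions:
        annotate(p, introns, coverage)
        ref_protein = proteins.get(p.reference_transcript_id)
        if ref_protein and p.protein:
            paa, iaa = alignment_stats(p.protein, ref_protein)
            p.attributes["pAA"] = paa
            p.attributes["iAA"] = iaa
    return predictions
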