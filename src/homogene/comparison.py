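"""Comparison of predictions with a reference annotation.

Provides best-overlap assignment of each prediction to the annotated CDS
maximizing the F1 of shared coding bases, tie/tpc annotation of an
existing annotation, and benchmark-style sensitivity/specificity/F1
evaluation at the gene, transcript and exon levels. All levels compare
CDS coordinates only.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .evidence_annotator import annotate
from .genome_io import ReferenceTranscript
from .model_builder import PredictedTranscript


@dataclass
class LevelMetrics:
    sn: float | None
    sp: float | None

    @property
    def f1(self) -> float | None:
        if self.sn is None or self.sp is None:
            return None
        if self.sn + self.sp == 0:
            return 0.0
        return 2 * self.sn * self.sp / (self.sn + self.sp)


@dataclass
class EvalReport:
    """Sn/Sp/F1 (percent) at gene, transcript and exon level."""

    gene: LevelMetrics
    transcript: LevelMetrics
    exon: LevelMetrics

    def as_dict(self) -> dict:
        out = {}
        for level in ("gene", "transcript", "exon"):
            m: LevelMetrics = getattr(self, level)
            out[level] = {"Sn": m.sn, "Sp": m.sp, "F1": m.f1}
        return out


def _coding_bases(t) -> set[tuple[str, int]]:
    return {(p.seq_id, pos) for p in t.parts for pos in range(p.start, p.end)}


def best_overlap(prediction: PredictedTranscript,
                 annotation: list[ReferenceTranscript]) -> tuple[str | None, float]:
    """Annotated CDS with the largest coding-base overlap, by F1.

    Precision is shared bases over predicted bases, recall shared over
    annotated; the transcript maximizing their harmonic mean is returned
    (ties: larger shared-base count, then lexicographic id). Returns
    ``(None, 0.0)`` when no annotated CDS shares a coding base.
    """
    pred_bases = _coding_bases(prediction)
    best_id, best = None, (0.0, 0, "")
    for t in annotation:
        if t.seq_id != prediction.seq_id or t.strand != prediction.strand:
            continue
        ann_bases = _coding_bases(t)
        shared = len(pred_bases & ann_bases)
        if shared == 0:
            continue
        precision = shared / len(pred_bases)
        recall = shared / len(ann_bases)
        f1 = 2 * precision * recall / (precision + recall)
        key = (f1, shared, t.transcript_id)
        if best_id is None or (f1, shared) > best[:2] or \
                ((f1, shared) == best[:2] and t.transcript_id < best[2]):
            best_id, best = t.transcript_id, key
    return best_id, best[0] if best_id is not None else 0.0


def annotation_evidence(annotation: list[ReferenceTranscript], introns,
                        coverage=None) -> pd.DataFrame:
    """tie and tpc of every annotated CDS, as a table."""
    rows = []
    for t in annotation:
        carrier = PredictedTranscript(
            prediction_id=t.transcript_id, reference_transcript_id=t.transcript_id,
            parts=t.parts, protein=t.protein, score=0.0, complete=t.complete)
        annotate(carrier, introns, coverage)
        rows.append({"transcript_id": t.transcript_id,
                     "tie": carrier.attributes["tie"],
                     "tpc": carrier.attributes["tpc"]})
    return pd.DataFrame(rows, columns=["transcript_id", "tie", "tpc"])


def _pct(num: int, denom: int) -> float | None:
    return 100.0 * num / denom if denom else None


def _transcript_key(t) -> tuple:
    parts = sorted((p.start, p.end) for p in t.parts)
    return (t.seq_id, t.strand, tuple(parts))


def evaluate(predicted: list[PredictedTranscript],
             annotated: list[ReferenceTranscript]) -> EvalReport:
    """Sensitivity and specificity at exon, transcript and gene level.

    An exon is correct iff an annotated CDS part with identical
    coordinates exists (duplicates counted once); a transcript is correct
    iff its full ordered part set is coordinate-identical; an annotated
    gene is found iff at least one of its transcripts is correctly
    predicted, and a predicted gene is correct iff at least one of its
    transcripts matches an annotated one.
    """
    ann_exons = {(p.seq_id, p.strand, p.start, p.end) for t in annotated for p in t.parts}
    pred_exons = {(p.seq_id, p.strand, p.start, p.end) for t in predicted for p in t.parts}
    exon = LevelMetrics(_pct(len(ann_exons & pred_exons), len(ann_exons)),
                        _pct(len(ann_exons & pred_exons), len(pred_exons)))

    ann_keys = {_transcript_key(t) for t in annotated}
    pred_keys = {_transcript_key(t) for t in predicted}
    tx_sn_num = sum(_transcript_key(t) in pred_keys for t in annotated)
    tx_sp_num = sum(_transcript_key(t) in ann_keys for t in predicted)
    transcript = LevelMetrics(_pct(tx_sn_num, len(annotated)),
                              _pct(tx_sp_num, len(predicted)))

    ann_genes: dict[str, bool] = {}
    for t in annotated:
        ann_genes[t.gene_id] = ann_genes.get(t.gene_id, False) or \
            (_transcript_key(t) in pred_keys)
    pred_genes: dict[str, bool] = {}
    for t in predicted:
        gid = t.attributes.get("gene") or t.prediction_id
        pred_genes[gid] = pred_genes.get(gid, False) or (_transcript_key(t) in ann_keys)
    gene = LevelMetrics(_pct(sum(ann_genes.values()), len(ann_genes)),
                        _pct(sum(pred_genes.values()), len(pred_genes)))
    return EvalReport(gene=gene, transcript=transcript, exon=exon)
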