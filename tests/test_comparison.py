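import numpy as np
import pytest

from homogene import (CodingPart, GenomeSequences, annotation_evidence, best_overlap,
                      evaluate, IntronEvidence)
from homogene.genome_io import build_transcript
from homogene.model_builder import PredictedTranscript

from .oracles import coding_base_sets_f1


def _annotated(tid, gid, intervals, genome=None, strand="+"):
    """Minimal annotated transcript (sequence content irrelevant here)."""
    if genome is None:
        size = max(b for _, b in intervals) + 3
        genome = GenomeSequences({"c": "A" * size})
    parts = [CodingPart("c", a, b, strand) for a, b in
             (intervals[::-1] if strand == "-" else intervals)]
    from homogene.genome_io import ReferenceTranscript
    return ReferenceTranscript(tid, gid, parts, "M", ["M"], [
        ((a.end, b.start) if strand == "+" else (a.start, b.end))
        for a, b in zip(parts, parts[1:])])


def _pred(pid, intervals, strand="+", gene=None):
    parts = [CodingPart("c", a, b, strand) for a, b in
             (intervals[::-1] if strand == "-" else intervals)]
    p = PredictedTranscript(prediction_id=pid, reference_transcript_id=pid,
                            parts=parts, protein="M", score=10.0, complete=True)
    if gene:
        p.attributes["gene"] = gene
    return p


def test_best_overlap_identity():
    ann = [_annotated("t1", "g1", [(0, 90)])]
    tid, f1 = best_overlap(_pred("p", [(0, 90)]), ann)
    assert tid == "t1" and f1 == 1.0


def test_best_overlap_half_coverage():
    ann = [_annotated("t1", "g1", [(0, 90)])]
    tid, f1 = best_overlap(_pred("p", [(0, 45)]), ann)
    assert tid == "t1" and f1 == pytest.approx(2 / 3)


def test_best_overlap_argmax():
    ann = [_annotated("small", "g1", [(0, 60)]), _annotated("big", "g2", [(100, 220)])]
    pred = _pred("p", [(30, 190)])   # shares 30 with small, 90 with big
    tid, _ = best_overlap(pred, ann)
    f_small = coding_base_sets_f1({("c", i) for i in range(30, 190)},
                                  {("c", i) for i in range(0, 60)})
    f_big = coding_base_sets_f1({("c", i) for i in range(30, 190)},
                                {("c", i) for i in range(100, 220)})
    assert f_big > f_small and tid == "big"


def test_best_overlap_none_when_disjoint():
    ann = [_annotated("t1", "g1", [(0, 30)])]
    assert best_overlap(_pred("p", [(500, 530)]), ann) == (None, 0.0)


def test_best_overlap_f1_one_iff_identical_base_sets():
    ann = [_annotated("t1", "g1", [(0, 30), (60, 90)])]
    same_bases = _pred("p", [(0, 30), (60, 90)])
    assert best_overlap(same_bases, ann)[1] == 1.0
    almost = _pred("q", [(0, 30), (60, 91)])
    assert best_overlap(almost, ann)[1] < 1.0


def test_best_overlap_matches_base_set_oracle():
    rng = np.random.default_rng(23)
    for _ in range(30):
        ann = []
        for i in range(3):
            s = int(rng.integers(0, 300))
            ann.append(_annotated(f"t{i}", f"g{i}", [(s, s + int(rng.integers(10, 120)))]))
        s = int(rng.integers(0, 300))
        pred = _pred("p", [(s, s + int(rng.integers(10, 120)))])
        tid, f1 = best_overlap(pred, ann)
        pred_bases = {("c", i) for p in pred.parts for i in range(p.start, p.end)}
        oracle = max((coding_base_sets_f1(
            pred_bases, {("c", i) for q in t.parts for i in range(q.start, q.end)})
            for t in ann), default=0.0)
        assert f1 == pytest.approx(oracle)


def test_evaluate_self_comparison_is_perfect(small_round_trip):
    truth = small_round_trip["truth"]
    as_preds = [_pred_from_ref(t) for t in truth]
    report = evaluate(as_preds, truth)
    for level in ("gene", "transcript", "exon"):
        m = getattr(report, level)
        assert m.sn == 100.0 and m.sp == 100.0 and m.f1 == 100.0


def _pred_from_ref(t):
    return PredictedTranscript(prediction_id=t.transcript_id,
                               reference_transcript_id=t.transcript_id,
                               parts=t.parts, protein=t.protein, score=1.0,
                               complete=t.complete)


def test_evaluate_counting_example():
    ann = [_annotated("t1", "g1", [(0, 90)]), _annotated("t2", "g2", [(200, 290)])]
    preds = [_pred("p1", [(0, 90)]), _pred("spurious", [(400, 490)])]
    report = evaluate(preds, ann)
    assert report.gene.sn == 50.0 and report.gene.sp == 50.0
    assert report.transcript.f1 == pytest.approx(50.0)


def test_f1_harmonic_mean():
    ann = [_annotated("t1", "g1", [(0, 90)])]
    preds = [_pred("p1", [(0, 90)]), _pred("p2", [(300, 390)])]
    report = evaluate(preds, ann)
    assert report.transcript.sn == 100.0 and report.transcript.sp == 50.0
    assert report.transcript.f1 == pytest.approx(200 / 3, abs=0.05)


def test_evaluate_monotonicity():
    ann = [_annotated("t1", "g1", [(0, 90)]), _annotated("t2", "g2", [(200, 290)])]
    correct = _pred("p1", [(0, 90)])
    base = evaluate([correct], ann)
    with_spurious = evaluate([correct, _pred("sp", [(500, 590)])], ann)
    assert with_spurious.gene.sp <= base.gene.sp
    with_more_correct = evaluate([correct, _pred("p2", [(200, 290)])], ann)
    assert with_more_correct.gene.sn >= base.gene.sn


def test_evaluate_empty_denominator_is_na():
    ann = [_annotated("t1", "g1", [(0, 90)])]
    report = evaluate([], ann)
    assert report.gene.sp is None and report.gene.f1 is None
    assert report.gene.sn == 0.0


def test_annotation_evidence_table(small_reference, true_introns):
    genome, refs = small_reference
    table = annotation_evidence(refs, true_introns)
    assert list(table.columns) == ["transcript_id", "tie", "tpc"]
    for _, row in table.iterrows():
        assert row["tie"] == 1.0          # every annotated intron is in evidence
        assert row["tpc"] is None or np.isnan(row["tpc"])


def test_annotation_evidence_single_exon_na():
    genome = GenomeSequences({"c": "ATGGTTTGGTAA"})
    t = build_transcript("t1", "g1", [CodingPart("c", 0, 12, "+")], genome)
    table = annotation_evidence([t], [IntronEvidence("c", 50, 90, "+", 3)])
    assert table.loc[0, "tie"] is None or np.isnan(table.loc[0, "tie"])
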