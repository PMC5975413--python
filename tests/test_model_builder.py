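import numpy as np
import pytest

from homogene import (GenomeSequences, IntronEvidence, evaluate, find_exon_hits,
                      predict)
from homogene.genome_io import STOP_CODONS, reverse_complement
from homogene.model_builder import assemble
from homogene.rnaseq_evidence import splice_candidates
from homogene import model_builder as mb


def _intron_motifs(genome, prediction):
    """(donor, acceptor) dinucleotides on the coding strand per intron."""
    seq = genome[prediction.seq_id]
    out = []
    for s, e in prediction.intron_intervals():
        if prediction.strand == "+":
            out.append((seq[s:s + 2], seq[e - 2:e]))
        else:
            rc = reverse_complement(seq[s:e])
            out.append((rc[:2], rc[-2:]))
    return out


def test_self_annotation_identity(small_reference, true_introns):
    genome, refs = small_reference
    preds = predict(refs, genome, introns=true_introns, k=1)
    assert len(preds) == len(refs)
    by_ref = {p.reference_transcript_id: p for p in preds}
    for t in refs:
        p = by_ref[t.transcript_id]
        assert [(q.start, q.end) for q in p.parts] == \
            [(q.start, q.end) for q in t.parts]
        assert p.strand == t.strand
        assert p.protein == t.protein
        assert p.complete


def test_two_planted_copies_ranked(small_reference):
    genome, refs = small_reference
    t = refs[0]
    s, e = t.span()
    locus = genome["chr1"][max(0, s - 60):e + 60]
    target = GenomeSequences({"dup": "A" * 150 + locus + "T" * 300 + locus + "A" * 150})
    preds = predict([t], target, k=2)
    assert len(preds) == 2
    assert preds[0].score >= preds[1].score
    spans = sorted(p.span()[0] for p in preds)
    assert spans[1] - spans[0] == 300 + len(locus)


def test_topk_ranking_consistency(small_reference):
    genome, refs = small_reference
    t = refs[0]
    s, e = t.span()
    locus = genome["chr1"][max(0, s - 60):e + 60]
    target = GenomeSequences({"dup": "A" * 150 + locus + "T" * 300 + locus + "A" * 150})
    top1 = predict([t], target, k=1)
    top10 = predict([t], target, k=10)
    assert [p.parts for p in top1] == [p.parts for p in top10[:1]]
    scores = [p.score for p in top10]
    assert scores == sorted(scores, reverse=True)


def test_empty_reference_list(small_reference):
    genome, _ = small_reference
    assert predict([], genome) == []


def test_dinucleotide_fallback_motifs(small_round_trip):
    """Without evidence, every predicted intron is GT/GC..AG on the coding strand."""
    preds = predict(small_round_trip["refs"], small_round_trip["target"],
                    introns=None, k=1)
    assert preds
    for p in preds:
        for donor, acceptor in _intron_motifs(small_round_trip["target"], p):
            assert donor in ("GT", "GC")
            assert acceptor == "AG"


def test_evidence_introns_selected_when_in_frame(small_round_trip):
    """With full split-read evidence, the predictions use exactly the
    evidence introns (intron position conservation fixture)."""
    introns = small_round_trip["introns"]
    evidence_set = {(i.seq_id, i.start, i.end) for i in introns}
    preds = predict(small_round_trip["refs"], small_round_trip["target"],
                    introns=introns, k=1)
    for p in preds:
        for s, e in p.intron_intervals():
            assert (p.seq_id, s, e) in evidence_set


def test_junction_prefers_maximal_scoring_evidence_pair(small_reference, true_introns):
    """Exhaustively rescoring the candidate set reproduces the builder's choice."""
    genome, refs = small_reference
    t = next(r for r in refs if r.strand == "+" and len(r.parts) >= 3)
    hits = find_exon_hits(t, genome)
    chain_hits = {}
    for h in hits:
        if h.strand == "+" and (h.part_index not in chain_hits
                                or h.score > chain_hits[h.part_index].score):
            chain_hits[h.part_index] = h
    h0, h1 = chain_hits[0], chain_hits[1]
    donors = splice_candidates((t.seq_id, h0.end - 30, h0.end + 32), "+",
                               true_introns, genome, "donor")
    acceptors = splice_candidates((t.seq_id, h1.start - 32, h1.start + 30), "+",
                                  true_introns, genome, "acceptor")
    best = mb.junction_combinations(h0, h1, donors, acceptors, t, 0,
                                    seq=genome["chr1"], upstream_start=h0.start,
                                    coding_len_before=0)
    assert best is not None
    donor, acceptor, _ = best
    assert (donor.pos, acceptor.pos) == t.intron_intervals()[0]
    assert donor.source == "evidence" and acceptor.source == "evidence"


def test_frame_shifting_intron_excluded(small_reference):
    """An evidence intron whose use shifts the frame by 1 is never combined."""
    genome, refs = small_reference
    t = next(r for r in refs if r.strand == "+" and len(r.parts) >= 2)
    (s, e) = t.intron_intervals()[0]
    shifted = [IntronEvidence(t.seq_id, s + 1, e, "+", 5)]
    hits = find_exon_hits(t, genome)
    best_by_part = {}
    for h in hits:
        if h.strand == "+" and (h.part_index not in best_by_part
                                or h.score > best_by_part[h.part_index].score):
            best_by_part[h.part_index] = h
    h0, h1 = best_by_part[0], best_by_part[1]
    donors = [c for c in splice_candidates((t.seq_id, h0.end - 30, h0.end + 32), "+",
                                           shifted, genome, "donor")
              if c.source == "evidence"]
    acceptors = [c for c in splice_candidates((t.seq_id, h1.start - 32, h1.start + 30),
                                              "+", shifted, genome, "acceptor")
                 if c.source == "evidence"]
    best = mb.junction_combinations(h0, h1, donors, acceptors, t, 0,
                                    seq=genome["chr1"], upstream_start=h0.start,
                                    coding_len_before=0)
    assert best is None


def test_planted_internal_stop_never_leaks(small_reference):
    genome, refs = small_reference
    t = next(r for r in refs if r.strand == "+" and len(r.parts) >= 2)
    contig = genome["chr1"]
    # plant an in-frame TAA in the middle of the first coding part
    p0 = t.parts[0]
    codon_offset = p0.start + 3 * ((len(p0) // 2) // 3)
    mutated = contig[:codon_offset] + "TAA" + contig[codon_offset + 3:]
    target = GenomeSequences({"chr1": mutated})
    preds = predict([t], target, k=1)
    for p in preds:
        assert "*" not in p.protein


def test_frame_and_monotone_ranking_invariants(small_round_trip):
    preds = predict(small_round_trip["refs"], small_round_trip["target"],
                    introns=small_round_trip["introns"], k=3)
    by_ref = {}
    for p in preds:
        by_ref.setdefault(p.reference_transcript_id, []).append(p)
        if p.complete:
            assert p.coding_length() % 3 == 0
            cds = "".join(small_round_trip["target"].fetch(q.seq_id, q.start, q.end,
                                                           p.strand) for q in p.parts)
            assert cds.startswith("ATG") and cds[-3:] in STOP_CODONS
    for group in by_ref.values():
        scores = [p.score for p in group]
        assert scores == sorted(scores, reverse=True)


def test_round_trip_recovery_small(small_round_trip):
    preds = predict(small_round_trip["refs"], small_round_trip["target"],
                    introns=small_round_trip["introns"], k=1)
    report = evaluate(preds, small_round_trip["truth"])
    assert report.transcript.sn >= 80.0
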