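"""Assembly of exon hits into complete gene models.

Hits of the reference coding parts are chained colinearly per target
sequence and strand, neighboring exons are joined by testing all in-frame
donor/acceptor combinations (experimental splice sites first, conserved
dinucleotides as fallback) scored against the reference peptide around the
intron, terminal exons are adjusted to a start and stop codon, and the
resulting models are scored by global alignment of the predicted against
the reference protein. Multiple ranked predictions per reference
transcript are returned; no filtering is applied at this stage.

All junction arithmetic is done on the plus strand: minus-strand chains
are mirrored into the reverse complement coordinate frame, assembled
there, and mirrored back.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from . import align as _align
from .genome_io import (STOP_CODONS, CodingPart, GenomeSequences, ReferenceTranscript,
                        compute_phases, reverse_complement, translate)
from .homology_search import ExonHit, find_exon_hits
from .rnaseq_evidence import (DEFAULT_MAX_INTRON, DEFAULT_MIN_INTRON, UNKNOWN,
                              IntronEvidence, SpliceSiteCandidate, splice_candidates)

logger = logging.getLogger(__name__)

DEFAULT_K = 10
SPLICE_WINDOW = 30
SPLICE_WINDOW_WIDE = 60
TERMINAL_WINDOW = 90          # nt searched for a start codon around the aligned start
STOP_SCAN_CODONS = 67         # codons scanned downstream for a stop
_JUNCTION_CONTEXT_AA = 16     # reference peptide context per side when scoring junctions


@dataclass
class PredictedTranscript:
    """An assembled gene model with score and evidence attributes."""

    prediction_id: str
    reference_transcript_id: str
    parts: list[CodingPart]
    protein: str
    score: float
    complete: bool
    attributes: dict = field(default_factory=dict)

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
        ordered = sorted(self.parts, key=lambda p: p.start)
        return [(a.end, b.start) for a, b in zip(ordered, ordered[1:])]

    def borders(self) -> tuple:
        """All part boundaries (splice sites, start and stop) as a sorted tuple."""
        pts = []
        for p in self.parts:
            pts.extend((p.start, p.end))
        return tuple(sorted(pts))

    def relative_score(self) -> float:
        """Score per protein residue (the spurious-prediction filter)."""
        if self.protein:
            return self.score / len(self.protein)
        # re-read predictions do not carry the protein; infer its length
        n_aa = self.coding_length() // 3 - (1 if self.complete else 0)
        return self.score / max(n_aa, 1)


# ---------------------------------------------------------------------------
# plus-strand working view

@dataclass
class _View:
    seq_id: str
    strand: str            # original strand this view represents
    seq: str               # sense-strand sequence (revcomp for '-')
    genome: GenomeSequences
    introns: list[IntronEvidence]

    @property
    def length(self) -> int:
        return len(self.seq)


def _make_view(seq_id: str, strand: str, target: GenomeSequences,
               introns: list[IntronEvidence] | None) -> _View:
    raw = target[seq_id]
    length = len(raw)
    seq = raw if strand == "+" else reverse_complement(raw)
    mirrored: list[IntronEvidence] = []
    for intron in introns or []:
        if intron.seq_id != seq_id:
            continue
        if intron.strand not in (strand, UNKNOWN):
            continue
        new_strand = "+" if intron.strand == strand else UNKNOWN
        if strand == "+":
            mirrored.append(IntronEvidence(seq_id, intron.start, intron.end,
                                           new_strand, intron.split_reads))
        else:
            mirrored.append(IntronEvidence(seq_id, length - intron.end,
                                           length - intron.start, new_strand,
                                           intron.split_reads))
    return _View(seq_id, strand, seq, GenomeSequences({seq_id: seq}), mirrored)


def _mirror_hit(hit: ExonHit, length: int) -> ExonHit:
    return ExonHit(hit.transcript_id, hit.part_index, hit.seq_id,
                   length - hit.end, length - hit.start, "+",
                   (length - hit.end) % 3, hit.score, hit.query_cover)


# ---------------------------------------------------------------------------
# junction resolution

def junction_combinations(upstream: ExonHit, downstream: ExonHit,
                          donors: list[SpliceSiteCandidate],
                          acceptors: list[SpliceSiteCandidate],
                          ref: ReferenceTranscript, intron_index: int, *,
                          seq: str, upstream_start: int, coding_len_before: int,
                          min_intron: int = DEFAULT_MIN_INTRON,
                          max_intron: int = DEFAULT_MAX_INTRON,
                          matrix_name: str = _align.DEFAULT_MATRIX,
                          gap_open: int = _align.DEFAULT_GAP_OPEN,
                          gap_extend: int = _align.DEFAULT_GAP_EXTEND,
                          ) -> tuple[SpliceSiteCandidate, SpliceSiteCandidate, float] | None:
    """Best in-frame (donor, acceptor) pair joining two neighboring exon hits.

    Every pair whose implied intron length lies within bounds and whose
    implied exon extension/truncation keeps the joined coding sequence in
    frame is scored by translating the junction region and globally
    aligning it to the reference peptide around the corresponding
    reference intron; the arg-max pair is returned. Ties prefer
    experimental evidence over dinucleotides, then minimal deviation of
    the intron position from the reference intron position, then the
    leftmost donor.
    """
    b_u, b_d = upstream.end, downstream.start
    up_idx = upstream.part_index
    down_idx = downstream.part_index
    ref_window = (ref.part_peptides[up_idx][-_JUNCTION_CONTEXT_AA:]
                  + ref.part_peptides[down_idx][:_JUNCTION_CONTEXT_AA])
    best = None
    best_key = None
    for donor in donors:
        d = donor.pos
        if d <= upstream_start:
            continue
        for acceptor in acceptors:
            a = acceptor.pos
            if a >= downstream.end:
                continue
            if not min_intron <= a - d <= max_intron:
                continue
            total = coding_len_before + (d - upstream_start)
            if (total + (b_d - a)) % 3 != 0:
                continue
            # translate the junction in the running codon frame
            js = max(upstream_start, d - 48)
            r = (coding_len_before + (js - upstream_start)) % 3
            js += (3 - r) % 3
            je = min(downstream.end, a + 48)
            junction_pep = translate(seq[js:d] + seq[a:je], 0)
            jscore = _align.semiglobal_score(junction_pep, ref_window,
                                             matrix_name, gap_open, gap_extend)
            evidence = donor.source == "evidence" and acceptor.source == "evidence"
            deviation = abs(d - b_u) + abs(a - b_d)
            key = (jscore, 1 if evidence else 0, -deviation, -d)
            if best_key is None or key > best_key:
                best_key = key
                best = (donor, acceptor, float(jscore))
    return best


# ---------------------------------------------------------------------------
# chaining

def _chain_hits(hits: list[ExonHit], min_intron: int, max_intron: int,
                max_chains: int) -> list[list[ExonHit]]:
    """Greedy extraction of high-scoring colinear hit chains."""
    order = sorted(range(len(hits)), key=lambda i: (hits[i].part_index, hits[i].start))
    hits = [hits[i] for i in order]
    n = len(hits)
    dp = [h.score for h in hits]
    prev = [-1] * n
    low_gap = max(4, min_intron - 24)
    for j in range(n):
        for i in range(j):
            if hits[i].part_index >= hits[j].part_index:
                continue
            gap = hits[j].start - hits[i].end
            span = hits[j].part_index - hits[i].part_index
            if gap < low_gap or gap > span * max_intron:
                continue
            cand = dp[i] + hits[j].score
            if cand > dp[j]:
                dp[j] = cand
                prev[j] = i
    used = [False] * n
    chains = []
    for j in sorted(range(n), key=lambda j: -dp[j]):
        if dp[j] <= 0:
            break
        chain_idx = []
        i = j
        while i != -1:
            chain_idx.append(i)
            i = prev[i]
        chain_idx.reverse()
        if any(used[i] for i in chain_idx):
            continue
        for i in chain_idx:
            used[i] = True
        chains.append([hits[i] for i in chain_idx])
        if len(chains) >= max_chains:
            break
    return chains


# ---------------------------------------------------------------------------
# model construction

def _adjust_start(seq: str, exons: list[list[int]], ref: ReferenceTranscript,
                  matrix_name: str, gap_open: int, gap_extend: int) -> bool:
    """Search an in-frame ATG around the aligned start; returns completeness."""
    s0, first_end = exons[0]
    if first_end - s0 < 3:
        return False
    candidates = []
    for t in range(-TERMINAL_WINDOW // 3, TERMINAL_WINDOW // 3 + 1):
        p = s0 + 3 * t
        if p < 0 or p + 3 > first_end:
            continue
        if seq[p:p + 3] != "ATG":
            continue
        if p < s0 and "*" in translate(seq[p:s0], 0):
            continue
        candidates.append(p)
    if not candidates:
        return False
    if len(candidates) > 1:
        scored = []
        for p in candidates:
            trial = [[p, first_end]] + exons[1:]
            cds = "".join(seq[a:b] for a, b in trial)
            protein = translate(cds, 0)
            stop = protein.find("*")
            if stop >= 0:
                protein = protein[:stop]
            s = _align.global_score(protein, ref.protein, matrix_name, gap_open, gap_extend)
            scored.append((s, -abs(p - s0), -p, p))
        candidates = [max(scored)[3]]
    exons[0][0] = candidates[0]
    return True


def _truncate_at_stop(seq: str, exons: list[list[int]]) -> tuple[list[list[int]], bool]:
    """Cut the exon list at the first in-frame stop codon, if any."""
    cds = "".join(seq[a:b] for a, b in exons)
    protein = translate(cds, 0)
    idx = protein.find("*")
    if idx < 0:
        return exons, cds[-3:] in STOP_CODONS and len(cds) % 3 == 0
    cut = 3 * idx + 3
    out = []
    cum = 0
    for a, b in exons:
        if cum + (b - a) >= cut:
            out.append([a, a + (cut - cum)])
            break
        out.append([a, b])
        cum += b - a
    return out, True


def _extend_to_stop(seq: str, exons: list[list[int]]) -> bool:
    """Scan downstream in frame for a stop codon and extend the last exon."""
    total = sum(b - a for a, b in exons)
    e = exons[-1][1]
    e -= total % 3                      # re-align a ragged end to the codon grid
    exons[-1][1] = e
    if exons[-1][1] - exons[-1][0] < 3:
        return False
    for t in range(STOP_SCAN_CODONS):
        codon = seq[e + 3 * t:e + 3 * t + 3]
        if len(codon) < 3:
            return False
        if codon in STOP_CODONS:
            exons[-1][1] = e + 3 * t + 3
            return True
    return False


def _build_model(chain: list[ExonHit], view: _View, ref: ReferenceTranscript, *,
                 min_intron: int, max_intron: int,
                 matrix_name: str, gap_open: int, gap_extend: int,
                 ) -> PredictedTranscript | None:
    seq = view.seq
    exons: list[list[int]] = []
    cur_start = chain[0].start
    coding_len = 0
    for h, h2 in zip(chain, chain[1:]):
        resolved = None
        for w in (SPLICE_WINDOW, SPLICE_WINDOW_WIDE):
            donors = splice_candidates(
                (view.seq_id, max(cur_start + 1, h.end - w), min(h.end + w + 2, view.length)),
                "+", view.introns, view.genome, "donor")
            acceptors = splice_candidates(
                (view.seq_id, max(0, h2.start - w - 2), min(h2.start + w, h2.end)),
                "+", view.introns, view.genome, "acceptor")
            resolved = junction_combinations(
                h, h2, donors, acceptors, ref, h.part_index,
                seq=seq, upstream_start=cur_start, coding_len_before=coding_len,
                min_intron=min_intron, max_intron=max_intron,
                matrix_name=matrix_name, gap_open=gap_open, gap_extend=gap_extend)
            if resolved is not None:
                break
        if resolved is None:
            logger.warning("unresolved junction after part %d of %s; model truncated",
                           h.part_index, ref.transcript_id)
            break
        donor, acceptor, _ = resolved
        exons.append([cur_start, donor.pos])
        coding_len += donor.pos - cur_start
        cur_start = acceptor.pos
    exons.append([cur_start, chain[len(exons)].end])

    complete_start = _adjust_start(seq, exons, ref, matrix_name, gap_open, gap_extend)
    exons, complete_end = _truncate_at_stop(seq, exons)
    if not complete_end:
        complete_end = _extend_to_stop(seq, exons)
    exons = [[a, b] for a, b in exons if b - a > 0]
    if not exons:
        return None

    cds = "".join(seq[a:b] for a, b in exons)
    protein = translate(cds, 0)
    if not protein:
        return None
    phases = compute_phases([b - a for a, b in exons], 0)
    if view.strand == "+":
        parts = [CodingPart(view.seq_id, a, b, "+", ph)
                 for (a, b), ph in zip(exons, phases)]
    else:
        length = view.length
        parts = [CodingPart(view.seq_id, length - b, length - a, "-", ph)
                 for (a, b), ph in zip(exons, phases)]
    score = _align.global_score(protein, ref.protein, matrix_name, gap_open, gap_extend)
    return PredictedTranscript(
        prediction_id="", reference_transcript_id=ref.transcript_id,
        parts=parts, protein=protein, score=float(score),
        complete=complete_start and complete_end,
        attributes={"ref_gene": ref.gene_id})


# ---------------------------------------------------------------------------
# public assembly API

def assemble(ref: ReferenceTranscript, hits: list[ExonHit], target: GenomeSequences,
             introns: list[IntronEvidence] | None = None, *,
             k: int = DEFAULT_K,
             min_intron: int = DEFAULT_MIN_INTRON,
             max_intron: int = DEFAULT_MAX_INTRON,
             matrix_name: str = _align.DEFAULT_MATRIX,
             gap_open: int = _align.DEFAULT_GAP_OPEN,
             gap_extend: int = _align.DEFAULT_GAP_EXTEND) -> list[PredictedTranscript]:
    """Assemble the hits of one reference transcript into ranked gene models."""
    groups: dict[tuple[str, str], list[ExonHit]] = {}
    for h in hits:
        if h.transcript_id != ref.transcript_id:
            continue
        groups.setdefault((h.seq_id, h.strand), []).append(h)

    models: list[PredictedTranscript] = []
    for (seq_id, strand), group in sorted(groups.items()):
        view = _make_view(seq_id, strand, target, introns)
        work = group if strand == "+" else [_mirror_hit(h, view.length) for h in group]
        for chain in _chain_hits(work, min_intron, max_intron, max_chains=max(k, 2)):
            model = _build_model(chain, view, ref,
                                 min_intron=min_intron, max_intron=max_intron,
                                 matrix_name=matrix_name, gap_open=gap_open,
                                 gap_extend=gap_extend)
            if model is not None and model.score > 0:
                models.append(model)

    models.sort(key=lambda m: (-m.score, m.seq_id, m.span()[0]))
    seen = set()
    unique = []
    for m in models:
        key = (m.seq_id, m.strand, tuple((p.start, p.end) for p in m.parts))
        if key in seen:
            continue
        seen.add(key)
        unique.append(m)
    unique = unique[:k]
    for rank, m in enumerate(unique, 1):
        m.prediction_id = f"{ref.transcript_id}_R{rank}"
    return unique


def predict(refs: list[ReferenceTranscript], target: GenomeSequences,
            introns: list[IntronEvidence] | None = None, *,
            k: int = DEFAULT_K,
            hits: dict[str, list[ExonHit]] | None = None,
            min_score_fraction: float | None = None,
            min_intron: int = DEFAULT_MIN_INTRON,
            max_intron: int = DEFAULT_MAX_INTRON) -> list[PredictedTranscript]:
    """Predict gene models on a target genome for all reference transcripts.

    ``hits`` may supply precomputed exon hits per transcript id (e.g. from
    an external search); otherwise the internal six-frame search is run.
    Predictions are not filtered; downstream filtering is the annotation
    filter's job.
    """
    from .homology_search import DEFAULT_MIN_SCORE_FRACTION
    frac = DEFAULT_MIN_SCORE_FRACTION if min_score_fraction is None else min_score_fraction
    out: list[PredictedTranscript] = []
    for ref in refs:
        ref_hits = hits.get(ref.transcript_id) if hits is not None else \
            find_exon_hits(ref, target, min_score_fraction=frac)
        if not ref_hits:
            continue
        out.extend(assemble(ref, ref_hits, target, introns, k=k,
                            min_intron=min_intron, max_intron=max_intron))
    return out
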