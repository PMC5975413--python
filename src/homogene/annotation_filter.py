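"""The annotation filter (GAF stage).

Combines raw predictions — possibly from several reference species — into
a final annotation: filter by relative score (score per protein residue),
merge border-identical predictions across species while counting the
supporting species (#evidence), cluster overlapping same-strand
predictions, pick the highest-scoring representative per cluster, keep
sufficiently similar members as alternative transcripts (common-border
filter), drop border-identical duplicates into the ``alternative``
attribute, and recover discarded predictions that overlap nothing kept as
nested genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .model_builder import PredictedTranscript

logger = logging.getLogger(__name__)

DEFAULT_RELATIVE_SCORE = 0.75
DEFAULT_COMMON_BORDER = 0.75


@dataclass
class Cluster:
    """Connected component of same-strand overlapping predictions."""

    seq_id: str
    strand: str
    span: tuple[int, int]
    members: list[PredictedTranscript] = field(default_factory=list)
    representative: str = ""


def _rank_key(p: PredictedTranscript):
    # higher score, then longer coding region, then leftmost, then id
    return (-p.score, -p.coding_length(), p.span()[0], p.prediction_id)


def filter_relative_score(predictions: list[PredictedTranscript],
                          threshold: float = DEFAULT_RELATIVE_SCORE) -> list[PredictedTranscript]:
    """Keep predictions whose score per protein residue reaches the threshold."""
    return [p for p in predictions if p.relative_score() >= threshold]


def filter_complete(predictions: list[PredictedTranscript]) -> list[PredictedTranscript]:
    return [p for p in predictions if p.complete]


def cluster(predictions: list[PredictedTranscript]) -> list[Cluster]:
    """Group same-strand predictions into overlap-connected components."""
    groups: dict[tuple[str, str], list[PredictedTranscript]] = {}
    for p in predictions:
        groups.setdefault((p.seq_id, p.strand), []).append(p)
    clusters = []
    for (seq_id, strand), members in sorted(groups.items()):
        members.sort(key=lambda p: p.span())
        open_members: list[PredictedTranscript] = []
        open_end = None
        for p in members:
            s, e = p.span()
            if open_end is None or s < open_end:
                open_members.append(p)
                open_end = e if open_end is None else max(open_end, e)
            else:
                clusters.append(_finish_cluster(seq_id, strand, open_members))
                open_members = [p]
                open_end = e
        if open_members:
            clusters.append(_finish_cluster(seq_id, strand, open_members))
    return clusters


def _finish_cluster(seq_id: str, strand: str, members: list[PredictedTranscript]) -> Cluster:
    span = (min(p.span()[0] for p in members), max(p.span()[1] for p in members))
    rep = min(members, key=_rank_key)
    return Cluster(seq_id, strand, span, members, rep.prediction_id)


def _border_fraction(a: tuple, b: tuple) -> float:
    """Shared borders relative to the smaller border set of the pair."""
    sa, sb = set(a), set(b)
    denom = min(len(sa), len(sb))
    return len(sa & sb) / denom if denom else 0.0


def _overlaps(p: PredictedTranscript, others: list[PredictedTranscript]) -> bool:
    # coding-exon overlap: a prediction inside another gene's intron does
    # not overlap it and can be recovered as a nested gene
    for o in others:
        for a in p.parts:
            for b in o.parts:
                if max(a.start, b.start) < min(a.end, b.end):
                    return True
    return False


def select(clust: Cluster, common_border_fraction: float = DEFAULT_COMMON_BORDER,
           ) -> tuple[list[list[PredictedTranscript]], dict[str, list[str]], list[PredictedTranscript]]:
    """Select the cluster's representative, alternatives and nested genes.

    Returns ``(genes, alternative_map, discarded)`` where ``genes`` is a
    list of transcript groups (the first group is the representative's
    gene, further groups are recovered nested genes), ``alternative_map``
    maps kept prediction ids to the ids of border-identical duplicates
    merged into them, and ``discarded`` lists members dropped entirely.
    """
    if not clust.members:
        raise ValueError("empty cluster")
    if not 0 < common_border_fraction <= 1:
        raise ValueError("common_border_fraction must be in (0, 1]")
    ordered = sorted(clust.members, key=_rank_key)
    representative = ordered[0]
    rep_borders = representative.borders()
    kept = [representative]
    alternative: dict[str, list[str]] = {}
    discarded: list[PredictedTranscript] = []
    for p in ordered[1:]:
        borders = p.borders()
        twin = next((q for q in kept if q.borders() == borders), None)
        if twin is not None:
            alternative.setdefault(twin.prediction_id, []).append(p.prediction_id)
            continue
        if _border_fraction(borders, rep_borders) >= common_border_fraction:
            kept.append(p)
        else:
            discarded.append(p)

    nested_candidates = [p for p in discarded if not _overlaps(p, kept)]
    remaining = [p for p in discarded if _overlaps(p, kept)]
    genes = [kept]
    if nested_candidates:
        for sub in cluster(nested_candidates):
            sub_genes, sub_alt, sub_disc = select(sub, common_border_fraction)
            genes.extend(sub_genes)
            alternative.update(sub_alt)
            remaining.extend(sub_disc)
    for kept_group in genes:
        for p in kept_group:
            if p.prediction_id in alternative:
                p.attributes["alternative"] = alternative[p.prediction_id]
    return genes, alternative, remaining


def count_evidence(predictions_by_species: dict[str, list[PredictedTranscript]],
                   ) -> list[PredictedTranscript]:
    """Merge border-identical predictions across species; set #evidence.

    Predictions with identical sequence, strand and border set from
    different reference species collapse into one record (the
    highest-ranked instance) whose ``evidence`` attribute counts the
    distinct supporting species; species-unique predictions get
    evidence 1.
    """
    merged: dict[tuple, tuple[PredictedTranscript, set[str]]] = {}
    for species, preds in predictions_by_species.items():
        for p in preds:
            key = (p.seq_id, p.strand, p.borders())
            if key not in merged:
                merged[key] = (p, {species})
            else:
                best, supporters = merged[key]
                supporters.add(species)
                if _rank_key(p) < _rank_key(best):
                    merged[key] = (p, supporters)
    out = []
    for p, supporters in merged.values():
        p.attributes["evidence"] = len(supporters)
        out.append(p)
    out.sort(key=lambda p: (p.seq_id, p.span()[0], p.prediction_id))
    return out


def filter_evidence(predictions: list[PredictedTranscript],
                    min_evidence: int = 1) -> list[PredictedTranscript]:
    return [p for p in predictions
            if p.attributes.get("evidence", 1) >= min_evidence]


def gaf(predictions_by_species: dict[str, list[PredictedTranscript]], *,
        relative_score: float = DEFAULT_RELATIVE_SCORE,
        common_border: float = DEFAULT_COMMON_BORDER,
        complete_only: bool = False,
        min_evidence: int = 1) -> list[PredictedTranscript]:
    """Run the full annotation filter over per-species prediction sets.

    Returns the kept transcripts with ``gene`` attributes assigned as
    generic names (gene_1, gene_2, ... in coordinate order).
    """
    filtered = {species: filter_relative_score(preds, relative_score)
                for species, preds in predictions_by_species.items()}
    pool = count_evidence(filtered)
    pool = filter_evidence(pool, min_evidence)
    if complete_only:
        pool = filter_complete(pool)

    gene_groups: list[list[PredictedTranscript]] = []
    for clust in cluster(pool):
        genes, _alt, dropped = select(clust, common_border)
        gene_groups.extend(genes)
        for p in dropped:
            logger.info("prediction %s discarded by the annotation filter", p.prediction_id)

    gene_groups.sort(key=lambda g: (g[0].seq_id, min(p.span()[0] for p in g)))
    out = []
    for i, group in enumerate(gene_groups, 1):
        for p in group:
            p.attributes["gene"] = f"gene_{i}"
            out.append(p)
    return out
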