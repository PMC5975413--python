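import pytest

from homogene import CodingPart, cluster, count_evidence, filter_relative_score, gaf, select
from homogene.annotation_filter import Cluster, filter_evidence
from homogene.model_builder import PredictedTranscript


def _pred(pid, intervals, strand="+", score=100.0, seq_id="c", complete=True):
    parts = [CodingPart(seq_id, a, b, strand) for a, b in
             (intervals[::-1] if strand == "-" else intervals)]
    n_aa = max(sum(b - a for a, b in intervals) // 3 - 1, 1)
    return PredictedTranscript(prediction_id=pid, reference_transcript_id=pid,
                               parts=parts, protein="M" * n_aa, score=score,
                               complete=complete)


def test_filter_relative_score():
    low = _pred("low", [(0, 303)], score=50.0)     # 100 aa, 0.5/res
    high = _pred("high", [(0, 303)], score=90.0)   # 0.9/res
    assert filter_relative_score([low, high], 0.75) == [high]
    assert filter_relative_score([low, high], float("-inf")) == [low, high]


def test_cluster_overlap_same_strand():
    a = _pred("a", [(0, 300)])
    b = _pred("b", [(200, 500)])
    (c,) = cluster([a, b])
    assert c.span == (0, 500) and len(c.members) == 2


def test_opposite_strands_never_merge():
    a = _pred("a", [(0, 300)], strand="+")
    b = _pred("b", [(0, 300)], strand="-")
    assert len(cluster([a, b])) == 2


def test_cluster_transitive_closure():
    a = _pred("a", [(0, 100)])
    b = _pred("b", [(90, 200)])
    c = _pred("c", [(190, 300)])
    (clust,) = cluster([a, b, c])       # a-b and b-c overlap, a-c do not
    assert {p.prediction_id for p in clust.members} == {"a", "b", "c"}


def test_representative_has_max_score():
    a = _pred("a", [(0, 300)], score=10.0)
    b = _pred("b", [(100, 400)], score=99.0)
    (c,) = cluster([a, b])
    assert c.representative == "b"


def test_identical_borders_deduplicated():
    a = _pred("a", [(0, 100), (150, 300)], score=90.0)
    b = _pred("b", [(0, 100), (150, 300)], score=80.0)
    (clust,) = cluster([a, b])
    genes, alt, dropped = select(clust)
    assert [p.prediction_id for p in genes[0]] == ["a"]
    assert alt == {"a": ["b"]}
    assert a.attributes["alternative"] == ["b"]
    assert dropped == []


def test_common_border_alternative_kept():
    rep = _pred("rep", [(0, 100), (150, 300)], score=90.0)     # 4 borders
    alt = _pred("alt", [(0, 100), (150, 320)], score=50.0)     # shares 3 of 4
    (clust,) = cluster([rep, alt])
    genes, _, dropped = select(clust, common_border_fraction=0.75)
    assert {p.prediction_id for p in genes[0]} == {"rep", "alt"}
    assert dropped == []
    genes_strict, _, dropped_strict = select(clust, common_border_fraction=0.9)
    assert {p.prediction_id for p in genes_strict[0]} == {"rep"}
    assert [p.prediction_id for p in dropped_strict] == ["alt"]


def test_nested_gene_recovered():
    host = _pred("host", [(0, 100), (900, 1000)], score=90.0)
    nested = _pred("nested", [(300, 600)], score=20.0)
    (clust,) = cluster([host, nested])
    genes, _, dropped = select(clust, common_border_fraction=0.75)
    assert [p.prediction_id for p in genes[0]] == ["host"]
    assert [[p.prediction_id for p in g] for g in genes[1:]] == [["nested"]]
    assert dropped == []


def test_count_evidence_merging():
    shared_a = _pred("sa", [(0, 100), (150, 300)], score=90.0)
    shared_b = _pred("sb", [(0, 100), (150, 300)], score=85.0)
    unique = _pred("u", [(400, 700)], score=70.0)
    merged = count_evidence({"sp1": [shared_a, unique], "sp2": [shared_b]})
    by_id = {p.prediction_id: p for p in merged}
    assert len(merged) == 2
    assert by_id["sa"].attributes["evidence"] == 2
    assert by_id["u"].attributes["evidence"] == 1
    assert filter_evidence(merged, 2) == [by_id["sa"]]


def test_gaf_no_identical_borders_and_gene_names():
    preds = {
        "sp1": [_pred("a", [(0, 100), (150, 300)], score=500.0),
                _pred("b", [(0, 100), (150, 300)], score=400.0),
                _pred("c", [(1000, 1300)], score=600.0)],
    }
    kept = gaf(preds, relative_score=0.0)
    borders = [p.borders() for p in kept]
    assert len(borders) == len(set(borders))
    assert sorted({p.attributes["gene"] for p in kept}) == ["gene_1", "gene_2"]


@pytest.mark.parametrize("attr,thresholds", [
    ("relative_score", [0.0, 1.0, 2.0, 3.0]),
    ("min_evidence", [1, 2, 3]),
])
def test_gaf_outputs_nested_under_increasing_thresholds(attr, thresholds):
    sets = {
        "sp1": [_pred("a1", [(0, 300)], score=900.0),
                _pred("b1", [(500, 800)], score=450.0)],
        "sp2": [_pred("a2", [(0, 300)], score=880.0),
                _pred("c2", [(1000, 1300)], score=100.0)],
    }
    previous = None
    for thr in thresholds:
        kwargs = {"relative_score": 0.0}
        if attr == "relative_score":
            kwargs["relative_score"] = thr
        else:
            kwargs["min_evidence"] = thr
        fresh = {sp: [_pred(p.prediction_id, [(q.start, q.end) for q in p.parts],
                            score=p.score) for p in preds]
                 for sp, preds in sets.items()}
        kept = {p.borders() for p in gaf(fresh, **kwargs)}
        if previous is not None:
            assert kept <= previous
        previous = kept


def test_every_member_accounted_for():
    members = [_pred("a", [(0, 100), (150, 300)], score=90.0),
               _pred("b", [(0, 100), (150, 300)], score=80.0),
               _pred("c", [(10, 90)], score=10.0),
               _pred("d", [(400, 500)], score=5.0)]
    # force one cluster artificially
    clust = Cluster("c", "+", (0, 500), members, "a")
    genes, alt, dropped = select(clust, 0.75)
    kept_ids = {p.prediction_id for g in genes for p in g}
    alt_ids = {i for ids in alt.values() for i in ids}
    dropped_ids = {p.prediction_id for p in dropped}
    assert kept_ids | alt_ids | dropped_ids == {"a", "b", "c", "d"}
    assert not (kept_ids & alt_ids) and not (kept_ids & dropped_ids)


def test_select_rejects_bad_fraction():
    clust = Cluster("c", "+", (0, 10), [_pred("a", [(0, 10)])], "a")
    with pytest.raises(ValueError):
        select(clust, 0.0)
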