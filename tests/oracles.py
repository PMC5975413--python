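"""Independent brute-force oracles used to check the implementation.

These are deliberately naive re-implementations (exhaustive DP, explicit
per-base counting) kept separate from the package code paths they verify.
"""

from __future__ import annotations

import re

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

NEG_INF = float("-inf")


def sw_affine_score(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Naive O(nm) Smith-Waterman with affine gaps.

    A gap of length k costs gap_open + k * gap_extend.
    """
    n, m = len(a), len(b)
    open_cost = gap_open + gap_extend
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in b (vertical)
    F = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in a (horizontal)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] - open_cost, E[i - 1][j] - gap_extend)
            F[i][j] = max(H[i][j - 1] - open_cost, F[i][j - 1] - gap_extend)
            diag = H[i - 1][j - 1] + _BLOSUM62[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def sam_intron_counts(sam_text: str, min_intron: int, max_intron: int):
    """Count N operations (within bounds) and aligned bases by CIGAR walking."""
    introns: dict[tuple[str, int, int], int] = {}
    aligned_bases = 0
    n_ops_in_bounds = 0
    for line in sam_text.splitlines():
        if not line or line.startswith("@"):
            continue
        fields = line.split("\t")
        flag = int(fields[1])
        if flag & 4 or fields[5] == "*":
            continue
        seq_id = fields[2]
        pos = int(fields[3]) - 1
        for count, op in _CIGAR_RE.findall(fields[5]):
            count = int(count)
            if op in "M=X":
                aligned_bases += count
                pos += count
            elif op == "N":
                if min_intron <= count <= max_intron:
                    key = (seq_id, pos, pos + count)
                    introns[key] = introns.get(key, 0) + 1
                    n_ops_in_bounds += 1
                pos += count
            elif op == "D":
                pos += count
    return introns, aligned_bases, n_ops_in_bounds


def evidence_stats(parts, strand: str, introns, coverage_arrays):
    """Brute-force tie/tpc/tae/tde/minCov/avgCov/minSplitReads.

    ``parts`` is a list of (seq_id, start, end) genomic intervals,
    ``introns`` a list of (seq_id, start, end, strand, count) tuples and
    ``coverage_arrays`` a mapping seq_id -> list of per-base depths (or
    None for no coverage).
    """
    parts = sorted(parts, key=lambda p: p[1])
    seq_id = parts[0][0]
    gaps = [(a[2], b[1]) for a, b in zip(parts, parts[1:])]
    usable = [(s, e, c) for sid, s, e, st, c in introns
              if sid == seq_id and st in (strand, "unknown")]

    stats = {}
    if not gaps:
        stats.update(tie=None, tae=None, tde=None, minSplitReads=None)
    else:
        counts = []
        for g in gaps:
            total = sum(c for s, e, c in usable if (s, e) == g)
            counts.append(total if total else None)
        stats["tie"] = sum(c is not None for c in counts) / len(gaps)
        starts = {s for s, e, c in usable}
        ends = {e for s, e, c in usable}
        if strand == "+":
            donor_hits = sum(g[0] in starts for g in gaps)
            acceptor_hits = sum(g[1] in ends for g in gaps)
        else:
            donor_hits = sum(g[1] in ends for g in gaps)
            acceptor_hits = sum(g[0] in starts for g in gaps)
        stats["tde"] = donor_hits / len(gaps)
        stats["tae"] = acceptor_hits / len(gaps)
        stats["minSplitReads"] = min(counts) if all(c is not None for c in counts) else None

    if coverage_arrays is None:
        stats.update(tpc=None, minCov=None, avgCov=None)
    else:
        depths = []
        arr = coverage_arrays.get(seq_id, [])
        for _, s, e in parts:
            for pos in range(s, e):
                depths.append(arr[pos] if 0 <= pos < len(arr) else 0)
        stats["tpc"] = sum(d > 0 for d in depths) / len(depths)
        stats["minCov"] = min(depths)
        stats["avgCov"] = sum(depths) / len(depths)
    return stats


def coding_base_sets_f1(pred_bases: set, ann_bases: set) -> float:
    shared = len(pred_bases & ann_bases)
    if shared == 0:
        return 0.0
    p = shared / len(pred_bases)
    r = shared / len(ann_bases)
    return 2 * p * r / (p + r)
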