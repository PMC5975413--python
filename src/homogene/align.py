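"""Pairwise protein alignment helpers shared across the pipeline.

All alignment in the package — the translated homology search, junction
scoring, prediction scoring and the pAA/iAA statistics — uses the same
substitution model: BLOSUM62 with affine gap costs in the BLAST convention,
where a gap of length ``k`` costs ``gap_open + k * gap_extend``
(default 11 + k).
"""

from __future__ import annotations

from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1


@lru_cache(maxsize=8)
def load_matrix(name: str = DEFAULT_MATRIX):
    return substitution_matrices.load(name)


def _make_aligner(mode: str, matrix_name: str, gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    if gap_open <= 0 or gap_extend <= 0:
        raise ValueError("gap penalties must be positive")
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = load_matrix(matrix_name)
    # BLAST convention: first gap position costs open+extend, later ones extend.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


@lru_cache(maxsize=32)
def local_aligner(matrix_name: str = DEFAULT_MATRIX,
                  gap_open: int = DEFAULT_GAP_OPEN,
                  gap_extend: int = DEFAULT_GAP_EXTEND) -> Align.PairwiseAligner:
    return _make_aligner("local", matrix_name, gap_open, gap_extend)


@lru_cache(maxsize=32)
def global_aligner(matrix_name: str = DEFAULT_MATRIX,
                   gap_open: int = DEFAULT_GAP_OPEN,
                   gap_extend: int = DEFAULT_GAP_EXTEND) -> Align.PairwiseAligner:
    return _make_aligner("global", matrix_name, gap_open, gap_extend)


@lru_cache(maxsize=32)
def semiglobal_aligner(matrix_name: str = DEFAULT_MATRIX,
                       gap_open: int = DEFAULT_GAP_OPEN,
                       gap_extend: int = DEFAULT_GAP_EXTEND) -> Align.PairwiseAligner:
    """Global alignment with free end gaps (overlap/glocal alignment).

    Used to score windows whose ends need not correspond exactly, e.g.
    the translated junction region against the reference peptide context.
    """
    aligner = _make_aligner("global", matrix_name, gap_open, gap_extend)
    aligner.end_gap_score = 0
    return aligner


def semiglobal_score(a: str, b: str,
                     matrix_name: str = DEFAULT_MATRIX,
                     gap_open: int = DEFAULT_GAP_OPEN,
                     gap_extend: int = DEFAULT_GAP_EXTEND) -> float:
    if not a or not b:
        return 0.0
    return semiglobal_aligner(matrix_name, gap_open, gap_extend).score(a, b)


def check_protein(seq: str, matrix_name: str = DEFAULT_MATRIX) -> None:
    """Reject symbols outside the substitution matrix alphabet."""
    alphabet = set(load_matrix(matrix_name).alphabet)
    bad = set(seq) - alphabet
    if bad:
        raise ValueError(f"non-amino-acid symbols in sequence: {sorted(bad)}")


def global_score(a: str, b: str,
                 matrix_name: str = DEFAULT_MATRIX,
                 gap_open: int = DEFAULT_GAP_OPEN,
                 gap_extend: int = DEFAULT_GAP_EXTEND) -> float:
    """Global (Needleman-Wunsch, affine) alignment score of two proteins."""
    if not a or not b:
        return 0.0
    return global_aligner(matrix_name, gap_open, gap_extend).score(a, b)


def self_score(peptide: str, matrix_name: str = DEFAULT_MATRIX) -> float:
    """Score of a peptide aligned to itself (sum of matrix diagonal)."""
    matrix = load_matrix(matrix_name)
    return float(sum(matrix[aa, aa] for aa in peptide))
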