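"""Pairwise sequence comparison.

Two comparison routes serve different stages of the homolog search:

* :func:`global_align` / :func:`percent_identity` — exact global (Needleman–
  Wunsch style) alignment with affine-like gap costs, used to score every
  extended BLAST hit against the query.  Percent identity (PI) computed here
  drives the true-homolog / candidate classification.
* :func:`ktuple_similarity` / :func:`ktuple_similarity_matrix` — the fast
  word-based identity estimate (Clustal Omega's k-tuple idea), used only for
  the coarse pre-grouping ahead of structure clustering, where an exact
  alignment per pair would be wasted effort.

Alphabet is nucleotide {A, C, G, T, U, N}; U is normalised to T and ``N``
never counts as a match (it scores as a mismatch and is excluded from the
identical-column count).
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "AlignmentParams",
    "GlobalAlignment",
    "InvalidSequenceError",
    "InvalidAlphabetError",
    "InvalidKError",
    "normalize_sequence",
    "global_align",
    "percent_identity",
    "ktuple_similarity",
    "ktuple_similarity_matrix",
]


class InvalidSequenceError(ValueError):
    """Empty or otherwise unusable input sequence."""


class InvalidAlphabetError(ValueError):
    """Sequence contains a character outside {A, C, G, T, U, N}."""


class InvalidKError(ValueError):
    """k-tuple word length incompatible with the sequences."""


_ALPHABET = "ACGTN"
_VALID = frozenset(_ALPHABET)


def normalize_sequence(seq: str, *, name: str = "sequence") -> str:
    """Uppercase, map U->T and validate the nucleotide alphabet."""
    if not isinstance(seq, str):
        seq = str(seq)
    s = seq.upper().replace("U", "T")
    if not s:
        raise InvalidSequenceError(f"{name} is empty")
    bad = set(s) - _VALID
    if bad:
        raise InvalidAlphabetError(
            f"{name} contains non-nucleotide characters: {sorted(bad)!r}"
        )
    return s


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring for the global alignment used in PI computation.

    Defaults follow the classic nucleotide scheme for sRNA homolog scoring:
    match +2, mismatch -1, and a mild affine gap cost where a gap of length
    ``g`` costs ``|gap_open| + (g - 1) * |gap_extend|``.  End gaps are
    penalised (true global mode).
    """

    match_score: float = 2.0
    mismatch_score: float = -1.0
    gap_open: float = -0.5
    gap_extend: float = -0.1

    def __post_init__(self) -> None:
        if self.match_score <= 0:
            raise ValueError("match_score must be positive")
        if self.mismatch_score > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("penalties must be <= 0")

    def _aligner(self) -> Align.PairwiseAligner:
        matrix = substitution_matrices.Array(_ALPHABET, dims=2)
        for x, y in itertools.product(_ALPHABET, repeat=2):
            if x == y and x != "N":
                matrix[x, y] = self.match_score
            else:
                matrix[x, y] = self.mismatch_score
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = matrix
        aligner.open_gap_score = self.gap_open
        aligner.extend_gap_score = self.gap_extend
        return aligner


@dataclass(frozen=True)
class GlobalAlignment:
    """One optimal global alignment plus its identity bookkeeping."""

    aligned_a: str
    aligned_b: str
    score: float
    n_identical: int
    n_columns: int

    @property
    def percent_identity(self) -> float:
        return 100.0 * self.n_identical / self.n_columns


def global_align(a: str, b: str, params: AlignmentParams | None = None) -> GlobalAlignment:
    """Optimal-score global alignment of two nucleotide sequences.

    Among co-optimal alignments the aligner's first (deterministic)
    traceback is reported; the score is optimal in every case.
    """
    params = params or AlignmentParams()
    sa = normalize_sequence(a, name="first sequence")
    sb = normalize_sequence(b, name="second sequence")
    aligner = params._aligner()
    alignment = next(iter(aligner.align(sa, sb)))
    aligned_a, aligned_b = str(alignment[0]), str(alignment[1])
    n_columns = len(aligned_a)
    n_identical = sum(
        1 for x, y in zip(aligned_a, aligned_b) if x == y and x not in "-N"
    )
    return GlobalAlignment(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(alignment.score),
        n_identical=n_identical,
        n_columns=n_columns,
    )


def percent_identity(a: str, b: str, params: AlignmentParams | None = None) -> float:
    """Global percent identity: identical columns / alignment columns x 100.

    The argument pair is put into a canonical order before aligning, so the
    result is exactly symmetric in its inputs.
    """
    sa = normalize_sequence(a, name="first sequence")
    sb = normalize_sequence(b, name="second sequence")
    if (len(sa), sa) > (len(sb), sb):
        sa, sb = sb, sa
    return global_align(sa, sb, params).percent_identity


def _kmer_counts(seq: str, k: int) -> Counter:
    return Counter(seq[i : i + k] for i in range(len(seq) - k + 1))


def ktuple_similarity(a: str, b: str, k: int = 2) -> float:
    """Word-based identity estimate on a 0-100 scale.

    Shared k-mers are counted with multiplicity, capped pairwise
    (``min(count_a, count_b)`` per word) and normalised by the number of
    words in the shorter sequence.
    """
    sa = normalize_sequence(a, name="first sequence")
    sb = normalize_sequence(b, name="second sequence")
    if k < 1 or k > min(len(sa), len(sb)):
        raise InvalidKError(f"k={k} incompatible with sequence lengths "
                            f"{len(sa)} and {len(sb)}")
    ca, cb = _kmer_counts(sa, k), _kmer_counts(sb, k)
    shared = sum(min(ca[w], cb[w]) for w in ca.keys() & cb.keys())
    denom = min(len(sa), len(sb)) - k + 1
    return 100.0 * shared / denom


def ktuple_similarity_matrix(seqs: list[str], k: int = 2) -> np.ndarray:
    """Symmetric k-tuple similarity matrix (percent scale, diagonal 100)."""
    if not seqs:
        raise InvalidSequenceError("need at least one sequence")
    norm = [normalize_sequence(s, name=f"sequence {i}") for i, s in enumerate(seqs)]
    shortest = min(len(s) for s in norm)
    if k < 1 or k > shortest:
        raise InvalidKError(f"k={k} exceeds shortest sequence length {shortest}")
    n = len(norm)
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = ktuple_similarity(norm[i], norm[j], k)
    return mat
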