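"""Affine-gap alignment and sequence identity.

The final arbiter of the cascade: surviving candidate pairs are aligned
globally under an affine gap model (Gotoh three-state dynamic programming,
via Biopython's ``PairwiseAligner``) and the identity is

    identity = matches / min(m, n)

— the matched columns of one score-maximizing alignment divided by the
shorter sequence's length. End gaps are free by default (semi-global), so a
short read overlapping a longer representative is not penalized for the
overhang; that choice pairs naturally with the shorter-length denominator.
N aligned against anything, including another N, scores and counts as a
mismatch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from Bio import Align, BiopythonDeprecationWarning
from Bio.Align import substitution_matrices

from .seqio import SequenceRecord

__all__ = ["ScoringScheme", "AlignmentResult", "align_affine", "identity_check"]

_ALPHABET = "ACGTN"


@dataclass(frozen=True)
class ScoringScheme:
    """Affine scoring parameters.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend`` (the opening
    position carries the open penalty). Defaults mirror common nucleotide
    clustering practice; only the identity definition is fixed by the method.
    """

    match: float = 2.0
    mismatch: float = -2.0
    gap_open: float = -6.0
    gap_extend: float = -1.0
    end_gaps_free: bool = True

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match reward must be positive")
        if self.mismatch > 0:
            raise ValueError("mismatch penalty must be <= 0")
        if not self.gap_open <= self.gap_extend <= 0:
            raise ValueError("require gap_open <= gap_extend <= 0")


@dataclass(frozen=True)
class AlignmentResult:
    score: float
    matches: int
    aligned_length: int
    identity: float


def _build_aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    matrix = substitution_matrices.Array(_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            matrix[a, b] = (
                scheme.match if (a == b and a != "N") else scheme.mismatch
            )
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = scheme.gap_open
    aligner.extend_gap_score = scheme.gap_extend
    if scheme.end_gaps_free:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", BiopythonDeprecationWarning)
            aligner.target_end_gap_score = 0.0
            aligner.query_end_gap_score = 0.0
    return aligner


_ALIGNER_CACHE: dict[ScoringScheme, Align.PairwiseAligner] = {}


def get_aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    """Cached Gotoh aligner for a scoring scheme."""
    aligner = _ALIGNER_CACHE.get(scheme)
    if aligner is None:
        aligner = _ALIGNER_CACHE[scheme] = _build_aligner(scheme)
    return aligner


def align_affine(
    q: SequenceRecord,
    r: SequenceRecord,
    scheme: ScoringScheme | None = None,
) -> AlignmentResult:
    """Optimal affine-gap alignment of q against r.

    The score maximizes over all global alignments (end gaps free when the
    scheme says so). Matches are counted from one score-maximizing traceback;
    co-optimal alignments may disagree on the match count, so the pair is put
    in a canonical orientation (longer sequence as target, ties broken
    lexicographically) and the first deterministic traceback of that
    orientation is used — identity is then a symmetric function of the pair.
    Identity is matches / min(|q|, |r|).
    """
    if q.length == 0 or r.length == 0:
        raise ValueError("cannot align an empty sequence")
    scheme = scheme or ScoringScheme()
    aligner = get_aligner(scheme)
    a, b = q, r
    if (a.length, a.seq) < (b.length, b.seq):
        a, b = b, a
    alignments = aligner.align(a.seq, b.seq)
    best = alignments[0]
    matches = 0
    tseq, qseq = a.seq, b.seq
    for (t0, t1), (q0, _q1) in zip(*best.aligned):
        for off in range(t1 - t0):
            a = tseq[t0 + off]
            if a != "N" and a == qseq[q0 + off]:
                matches += 1
    n = min(q.length, r.length)
    return AlignmentResult(
        score=float(best.score),
        matches=matches,
        aligned_length=int(best.shape[1]),
        identity=matches / n,
    )


def identity_check(result: AlignmentResult, s: float) -> bool:
    """Same-cluster decision: identity >= s (inclusive boundary)."""
    if not 0.0 < s <= 1.0:
        raise ValueError("identity threshold s must be in (0, 1]")
    return result.identity >= s
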