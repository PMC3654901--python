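"""Longest-common-subsequence filtering.

The second filter of the cascade, and the heart of the method. For two
sequences X (length m) and Y (length n <= m), the LCS length LLCS(X, Y)
equals the number of matches in the match-maximizing alignment, so

    LLCS(X, Y) / n  >=  sequence identity

for *any* score-optimal alignment whose identity is matches / n. A pair can
therefore be rejected before alignment whenever LLCS/n falls below the
identity threshold s, and a pair whose true identity reaches s can never be
rejected — the filter has no false negatives and reuses s itself as its
criterion, with no extra tuning knob.

LLCS is computed by a Hyyro-family bit-parallel algorithm. A position-mask
set PM over X (one m-bit vector per symbol, LSB = position 0) is built once
per representative in O(sigma*ceil(m/w) + m); each query is then scanned in
O(ceil(m/w)) word operations per character, i.e. O(sigma*ceil(m/w)*n)
overall, using the row update

    U <- V & PM[y_j]
    V <- (V + U) | (V - U)

with V initialized to all ones; LLCS is the number of cleared bits among the
low m bits of the final V. Vectors are stored as ceil(m/w) blocks of w bits
and the addition's carries are chained across blocks explicitly. (U is
bitwise a subset of V, so V - U never borrows across blocks and reduces to
V ^ U per block.) The O(mn) dynamic-programming recurrence is kept as
``llcs_dp``, the ground-truth oracle the kernel is verified against.

N is treated as matching nothing, including another N: an ambiguous base
must not inflate the identity upper bound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import SequenceRecord

__all__ = [
    "PositionMaskSet",
    "compute_pm",
    "llcs_dp",
    "llcs_bitparallel",
    "lcs_filter",
]

DEFAULT_WORD_WIDTH = 64


@dataclass
class PositionMaskSet:
    """Per-symbol position bit masks over one sequence X.

    ``masks[c]`` (c in 0..3 for A,C,G,T) is a list of ``ceil(m/w)`` blocks of
    ``w`` bits; bit i (LSB = position 0) of the concatenated vector is set
    iff X[i] equals the symbol. N positions are set in no mask, so the four
    masks are pairwise disjoint and their union covers exactly the non-N
    positions.
    """

    masks: list[list[int]]
    m: int
    w: int = DEFAULT_WORD_WIDTH

    @property
    def num_blocks(self) -> int:
        return len(self.masks[0]) if self.masks else 0


def compute_pm(X: SequenceRecord, w: int = DEFAULT_WORD_WIDTH) -> PositionMaskSet:
    """Build the position-mask set for X with word width w."""
    if w < 1:
        raise ValueError("word width must be >= 1")
    m = X.length
    nb = (m + w - 1) // w if m else 0
    wmask = (1 << w) - 1
    wide = [0, 0, 0, 0]
    for i, b in enumerate(X.encoded):
        if b < 4:
            wide[b] |= 1 << i
    masks = [
        [(wide[c] >> (blk * w)) & wmask for blk in range(nb)] for c in range(4)
    ]
    return PositionMaskSet(masks=masks, m=m, w=w)


def llcs_dp(X: SequenceRecord | str, Y: SequenceRecord | str) -> int:
    """LCS length by the textbook O(mn) dynamic programme.

    Row i is obtained from row i-1 as ``cur = cummax(max(prev, prev_shift +
    eq))``, which is the standard recurrence with the left-neighbour
    dependency folded into a prefix maximum. Serves as the ground-truth
    oracle for the bit-parallel kernel. N matches nothing, including N.
    """
    x = X.encoded if isinstance(X, SequenceRecord) else SequenceRecord("x", X).encoded
    y = Y.encoded if isinstance(Y, SequenceRecord) else SequenceRecord("y", Y).encoded
    m, n = len(x), len(y)
    if m == 0 or n == 0:
        return 0
    yv = y.astype(np.int64)
    valid = yv != 4
    prev = np.zeros(n + 1, dtype=np.int64)
    cur = np.empty(n + 1, dtype=np.int64)
    for i in range(m):
        xi = int(x[i])
        eq = (yv == xi) & valid if xi != 4 else np.zeros(n, dtype=bool)
        cur[0] = 0
        np.maximum(prev[1:], prev[:-1] + eq, out=cur[1:])
        np.maximum.accumulate(cur, out=cur)
        prev, cur = cur, prev
    return int(prev[n])


def llcs_bitparallel(pm: PositionMaskSet, Y: SequenceRecord | str) -> int:
    """LCS length of (X, Y) from the position masks of X.

    Exactly equals ``llcs_dp(X, Y)`` for all inputs; runs in
    O(ceil(m/w)) blocked word operations per character of Y, with addition
    carries propagated across adjacent blocks.
    """
    y = Y.encoded if isinstance(Y, SequenceRecord) else SequenceRecord("y", Y).encoded
    m, w = pm.m, pm.w
    nb = pm.num_blocks
    if m == 0 or len(y) == 0:
        return 0
    wmask = (1 << w) - 1
    V = [wmask] * nb
    masks = pm.masks
    for b in y:
        if b == 4:  # N: empty mask, V + 0 | V ^ 0 leaves V unchanged
            continue
        pmc = masks[b]
        carry = 0
        for blk in range(nb):
            v = V[blk]
            u = v & pmc[blk]
            s = v + u + carry
            carry = s >> w
            # V - U == V ^ U blockwise: U's bits are a subset of V's
            V[blk] = (s & wmask) | (v ^ u)
    zeros = 0
    for blk in range(nb):
        lo = blk * w
        width = min(w, m - lo)
        if width <= 0:
            break
        zeros += width - (V[blk] & ((1 << width) - 1)).bit_count()
    return zeros


def lcs_filter(
    q: SequenceRecord,
    r: SequenceRecord,
    s: float,
    pm: PositionMaskSet | None = None,
) -> bool:
    """Pass iff LLCS(q, r) / min(|q|, |r|) >= s.

    The ratio is an upper bound on the alignment identity, so every pair
    whose identity reaches s passes; pairs that fail are certainly below s.
    ``pm`` may carry precomputed position masks of ``r`` (the cluster
    representative), amortizing their construction across queries.
    """
    if not 0.0 < s <= 1.0:
        raise ValueError("identity threshold s must be in (0, 1]")
    n = min(q.length, r.length)
    if n == 0:
        return False
    if pm is None:
        pm = compute_pm(r)
    llcs = llcs_bitparallel(pm, q)
    return llcs / n >= s
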