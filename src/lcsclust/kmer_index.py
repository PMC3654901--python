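"""Modified short-word (k-mer) filter.

The first, cheap candidate filter of the clustering cascade. Unlike CD-HIT,
which registers *all* k-mers of a representative, only every k-th k-mer of a
representative is registered (plus one tail word so the final bases stay
visible); the query side still enumerates all of its k-mers. This shrinks the
word table to roughly 1/k of the all-words size, at the price of a lower
common-word threshold t — the stricter LCS filter downstream absorbs the
extra false positives.

k-mers are radix-4 coded (A=0, C=1, G=2, T=3); any window containing an N has
no defined code and is skipped on both the registration and the query side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .seqio import SequenceRecord

__all__ = [
    "ShortWordTable",
    "CandidateSet",
    "register_representative",
    "find_candidates",
    "default_word_threshold",
    "enumerate_kmers",
]

logger = logging.getLogger(__name__)

#: Largest k for which a direct-address table of 4**k buckets is used.
_DIRECT_ADDRESS_MAX_K = 12


@dataclass
class CandidateSet:
    """Representatives sharing at least t k-mers with one query."""

    query_index: int
    #: (representative index, common k-mer count >= t), ordered by rep index.
    hits: list[tuple[int, int]] = field(default_factory=list)

    def indices(self) -> list[int]:
        return [r for r, _ in self.hits]


class ShortWordTable:
    """Index from k-mer code to the representatives registered under it.

    For k <= 12 the table is direct-addressed with 4**k buckets (4**9 =
    262,144 — small); above that a hash map is used. Buckets are append-only
    lists of ``(representative index, registered position)``.
    """

    def __init__(self, k: int = 9):
        if k < 1:
            raise ValueError("word length k must be >= 1")
        self.k = k
        self._direct = k <= _DIRECT_ADDRESS_MAX_K
        if self._direct:
            self._buckets: list | dict = [None] * (4**k)
        else:
            self._buckets = {}
        #: per-representative number of registered words (diagnostics).
        self.words_per_rep: dict[int, int] = {}

    @property
    def num_entries(self) -> int:
        """Addressable codes; at least 4**k by construction."""
        return 4**self.k

    def bucket(self, code: int) -> list[tuple[int, int]]:
        if self._direct:
            b = self._buckets[code]
        else:
            b = self._buckets.get(code)
        return b if b is not None else []

    def _append(self, code: int, rep_index: int, pos: int) -> None:
        if self._direct:
            b = self._buckets[code]
            if b is None:
                b = self._buckets[code] = []
        else:
            b = self._buckets.setdefault(code, [])
        b.append((rep_index, pos))


def enumerate_kmers(
    rec: SequenceRecord, k: int, step: int = 1
) -> list[tuple[int, int]]:
    """Enumerate (position, radix-4 code) for k-mers at stride ``step``.

    Windows containing an N are skipped. 0-based positions.
    """
    enc = rec.encoded
    L = len(enc)
    out: list[tuple[int, int]] = []
    if L < k:
        return out
    if step == 1:
        # rolling code over all positions
        code = 0
        mask = 4**k
        last_n = -1  # most recent N position seen
        for i in range(L):
            b = int(enc[i])
            if b == 4:
                last_n = i
                code = (code * 4) % mask
                continue
            code = (code * 4 + b) % mask
            start = i - k + 1
            if start >= 0 and last_n < start:
                out.append((start, code))
        return out
    positions = list(range(0, L - k + 1, step))
    tail = L - k
    if positions and positions[-1] != tail:
        positions.append(tail)
    for p in positions:
        window = enc[p : p + k]
        if (window == 4).any():
            continue
        code = 0
        for b in window:
            code = code * 4 + int(b)
        out.append((p, code))
    return out


def register_representative(
    table: ShortWordTable, rep: SequenceRecord, rep_index: int
) -> ShortWordTable:
    """Register every k-th k-mer of a new representative into the table.

    Words start at positions 0, k, 2k, ...; when the last stride does not
    land on the final window, the k-mer ending at the last base is registered
    as well, so the tail of the representative is not invisible to the
    filter. A representative shorter than k registers zero words (warning,
    never an exception) and can only ever be reached by the aligner through
    no candidate — it stays a singleton.
    """
    k = table.k
    if rep.length < k:
        logger.warning(
            "representative %r (length %d) is shorter than k=%d; "
            "registered with zero words",
            rep.id,
            rep.length,
            k,
        )
        table.words_per_rep[rep_index] = 0
        return table
    words = enumerate_kmers(rep, k, step=k)
    for pos, code in words:
        table._append(code, rep_index, pos)
    table.words_per_rep[rep_index] = len(words)
    return table


def find_candidates(
    table: ShortWordTable, query: SequenceRecord, t: int
) -> CandidateSet:
    """Representatives sharing >= t k-mers with the query.

    All k-mers of the query are enumerated; for each representative the count
    is the number of *query positions* whose word is registered for that
    representative (representative-side multiplicity is ignored). Hits are
    returned in representative-creation order.
    """
    if t < 1:
        raise ValueError("word threshold t must be >= 1")
    cs = CandidateSet(query_index=-1)
    if query.length < table.k:
        return cs
    counts: dict[int, int] = {}
    reps_by_code: dict[int, list[int]] = {}
    for _pos, code in enumerate_kmers(query, table.k, step=1):
        reps = reps_by_code.get(code)
        if reps is None:
            bucket = table.bucket(code)
            if bucket:
                seen: set[int] = set()
                reps = [r for r, _ in bucket if not (r in seen or seen.add(r))]
            else:
                reps = []
            reps_by_code[code] = reps
        for r in reps:
            counts[r] = counts.get(r, 0) + 1
    cs.hits = sorted((r, c) for r, c in counts.items() if c >= t)
    return cs


def default_word_threshold(read_length: int) -> int:
    """Default common-word threshold t for a given read length.

    Short reads (<= 200 bases) use t=1; longer reads use t=4. These are the
    operating points used with k=9 at identity threshold 0.9; ideally t
    scales as ceil(t'/k) where t' is the all-words threshold of a CD-HIT-style
    filter, but t' is application-specific, so the two-level default is
    exposed instead and fully overridable.
    """
    if read_length < 1:
        raise ValueError("read length must be >= 1")
    return 1 if read_length <= 200 else 4
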