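"""Independent brute-force oracles used only by the test suite.

Deliberately naive: the LCS oracle enumerates subsequences, the alignment
oracle enumerates complete alignments. Neither shares code with the package
paths they verify.
"""

from __future__ import annotations

from lcsclust.align import ScoringScheme


def random_dna(rng, n: int, alphabet: str = "ACGT") -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=n))


def llcs_brute(x: str, y: str) -> int:
    """LCS length by enumerating all subsequences of x (len(x) <= ~12).

    N is ambiguous and never matches, so subsequences containing N are not
    common subsequences of anything.
    """
    best = 0
    for mask in range(1 << len(x)):
        sub = [x[i] for i in range(len(x)) if (mask >> i) & 1]
        if len(sub) <= best or "N" in sub:
            continue
        it = iter(y)
        if all(c in it for c in sub):
            best = len(sub)
    return best


def affine_score_brute(x: str, y: str, scheme: ScoringScheme) -> float:
    """Maximum affine-gap global alignment score by full enumeration.

    Alignments are sequences of column operations M (consume both), D
    (consume x only) and I (consume y only). A gap run of length L costs
    gap_open + (L-1) * gap_extend; runs touching either end of the alignment
    are free when the scheme is end-gaps-free.
    """
    m, n = len(x), len(y)
    best = float("-inf")
    ops: list[str] = []

    def score() -> float:
        total = 0.0
        i = j = 0
        c = 0
        L = len(ops)
        while c < L:
            op = ops[c]
            if op == "M":
                a, b = x[i], y[j]
                total += scheme.match if (a == b and a != "N") else scheme.mismatch
                i += 1
                j += 1
                c += 1
                continue
            run_start = c
            while c < L and ops[c] == op:
                if op == "D":
                    i += 1
                else:
                    j += 1
                c += 1
            run_len = c - run_start
            if scheme.end_gaps_free and (run_start == 0 or c == L):
                continue
            total += scheme.gap_open + (run_len - 1) * scheme.gap_extend
        return total

    def rec(i: int, j: int) -> None:
        nonlocal best
        if i == m and j == n:
            s = score()
            if s > best:
                best = s
            return
        if i < m and j < n:
            ops.append("M")
            rec(i + 1, j + 1)
            ops.pop()
        if i < m:
            ops.append("D")
            rec(i + 1, j)
            ops.pop()
        if j < n:
            ops.append("I")
            rec(i, j + 1)
            ops.pop()

    rec(0, 0)
    return best
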