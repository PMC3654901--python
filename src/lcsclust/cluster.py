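"""Greedy incremental clustering engine.

Sequences are processed one at a time. Each query q is compared against the
set R of existing cluster representatives through a three-stage cascade:

1. short-word filter — representatives sharing >= t k-mers with q;
2. LCS filter — survivors whose LLCS/n upper bound reaches the identity
   threshold s (no false negatives);
3. affine-gap alignment — survivors aligned in representative-creation
   order; q joins the first (or, optionally, best) cluster whose identity
   >= s.

If no cluster accepts q, it founds a new cluster, becomes its permanent
representative, and is registered in the short word table. Representatives
are never updated, so the outcome depends on processing order; the default
orders reads by decreasing length so longer representatives absorb shorter
reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import kmer_index, lcs
from .align import ScoringScheme, align_affine, identity_check
from .seqio import SequenceRecord

__all__ = [
    "ClusterConfig",
    "Cluster",
    "ClusteringResult",
    "StageCounts",
    "cluster_greedy",
    "order_sequences",
    "verify_result",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClusterConfig:
    """Run parameters for one clustering pass.

    s : identity threshold in (0, 1]; a member's identity to its
        representative is always >= s.
    k : short-word length in bases.
    t : common-word threshold, or "auto" (1 for reads <= 200 bases, 4 above,
        resolved from the median input length).
    ordering : "length_desc" (stable decreasing length) or "input".
    assignment : "first" (join the earliest-created accepting cluster) or
        "best" (highest identity among accepting clusters).
    """

    s: float = 0.9
    k: int = 9
    t: int | str = "auto"
    ordering: str = "length_desc"
    assignment: str = "first"
    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    word_width: int = lcs.DEFAULT_WORD_WIDTH

    def __post_init__(self) -> None:
        if not 0.0 < self.s <= 1.0:
            raise ValueError("identity threshold s must be in (0, 1]")
        if self.k < 1:
            raise ValueError("word length k must be >= 1")
        if self.t != "auto" and (not isinstance(self.t, int) or self.t < 1):
            raise ValueError('word threshold t must be an integer >= 1 or "auto"')
        if self.ordering not in ("input", "length_desc"):
            raise ValueError("ordering must be 'input' or 'length_desc'")
        if self.assignment not in ("first", "best"):
            raise ValueError("assignment must be 'first' or 'best'")


@dataclass
class Cluster:
    """One cluster: a fixed representative plus its members."""

    representative: int  # index into the input record list
    creation_order: int
    #: (record index, identity to the representative); includes the
    #: representative itself at identity 1.0.
    members: list[tuple[int, float]] = field(default_factory=list)

    def size(self) -> int:
        return len(self.members)


@dataclass
class StageCounts:
    """Per-stage pair counts, mirroring the filtering-efficiency diagnostics."""

    queries: int = 0
    shortword_pairs: int = 0  # pairs passing the short-word filter
    lcs_pairs: int = 0  # of those, pairs passing the LCS filter
    aligned_pairs: int = 0  # pairs actually aligned (first-hit may stop early)
    accepted_pairs: int = 0  # alignments reaching identity >= s
    new_clusters: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


@dataclass
class ClusteringResult:
    clusters: list[Cluster]
    records: list[SequenceRecord]
    config: ClusterConfig
    #: record index -> cluster index; a partition of the input.
    assignments: dict[int, int]
    stage_counts: StageCounts
    processing_order: list[int]

    @property
    def representatives(self) -> list[int]:
        return [c.representative for c in self.clusters]

    def summary(self) -> str:
        sc = self.stage_counts
        lines = [
            f"sequences: {len(self.records)}",
            f"clusters: {len(self.clusters)}",
            f"short-word filter pairs passed: {sc.shortword_pairs}",
            f"LCS filter pairs passed: {sc.lcs_pairs}",
            f"alignments computed: {sc.aligned_pairs}",
            f"alignments accepted (identity >= {self.config.s}): {sc.accepted_pairs}",
        ]
        return "\n".join(lines)


def order_sequences(
    sequences: list[SequenceRecord], policy: str = "length_desc"
) -> list[int]:
    """Processing order as a list of indices into ``sequences``.

    ``input`` keeps file order; ``length_desc`` stably sorts by decreasing
    length (ties keep input order).
    """
    if policy == "input":
        return list(range(len(sequences)))
    if policy == "length_desc":
        return sorted(range(len(sequences)), key=lambda i: -sequences[i].length)
    raise ValueError(f"unknown ordering policy {policy!r}")


def _resolve_t(config: ClusterConfig, records: list[SequenceRecord]) -> int:
    if config.t != "auto":
        return int(config.t)
    if not records:
        return 1
    median_len = int(np.median([r.length for r in records]))
    t = kmer_index.default_word_threshold(max(median_len, 1))
    logger.info("auto word threshold t=%d (median read length %d)", t, median_len)
    return t


def cluster_greedy(
    sequences: list[SequenceRecord], config: ClusterConfig | None = None
) -> ClusteringResult:
    """Cluster records greedily through the two-filter cascade.

    Pathological inputs are safe: reads shorter than k or made entirely of N
    produce no k-mers, reach no candidates, and found singleton clusters.
    """
    config = config or ClusterConfig()
    t = _resolve_t(config, sequences)
    order = order_sequences(sequences, config.ordering)
    table = kmer_index.ShortWordTable(config.k)
    clusters: list[Cluster] = []
    assignments: dict[int, int] = {}
    pm_cache: dict[int, lcs.PositionMaskSet] = {}  # cluster idx -> PM of rep
    counts = StageCounts()

    for qi in order:
        q = sequences[qi]
        counts.queries += 1
        cand = kmer_index.find_candidates(table, q, t)
        counts.shortword_pairs += len(cand.hits)

        # (b)(i) LCS filtering of every short-word survivor
        survivors: list[int] = []
        for ci, _common in cand.hits:
            rep = sequences[clusters[ci].representative]
            pm = pm_cache.get(ci)
            if pm is None:
                pm = pm_cache[ci] = lcs.compute_pm(rep, config.word_width)
            if lcs.lcs_filter(q, rep, config.s, pm=pm):
                survivors.append(ci)
        counts.lcs_pairs += len(survivors)

        # (b)(ii) alignment of saved pairs, in representative-creation order
        chosen: int | None = None
        chosen_identity = 0.0
        for ci in survivors:
            rep = sequences[clusters[ci].representative]
            counts.aligned_pairs += 1
            res = align_affine(q, rep, config.scheme)
            if identity_check(res, config.s):
                counts.accepted_pairs += 1
                if config.assignment == "first":
                    chosen, chosen_identity = ci, res.identity
                    break
                if res.identity > chosen_identity:
                    chosen, chosen_identity = ci, res.identity

        if chosen is not None:
            clusters[chosen].members.append((qi, chosen_identity))
            assignments[qi] = chosen
        else:
            # (c) found a new cluster; register q in the short word table
            ci = len(clusters)
            clusters.append(
                Cluster(representative=qi, creation_order=ci, members=[(qi, 1.0)])
            )
            assignments[qi] = ci
            kmer_index.register_representative(table, q, ci)
            counts.new_clusters += 1

        if counts.queries % 5000 == 0:
            logger.info(
                "processed %d sequences, %d clusters", counts.queries, len(clusters)
            )

    return ClusteringResult(
        clusters=clusters,
        records=sequences,
        config=config,
        assignments=assignments,
        stage_counts=counts,
        processing_order=order,
    )


def verify_result(result: ClusteringResult) -> list[tuple[int, int, float]]:
    """Re-align every member to its representative; return violations.

    Each violation is (record index, cluster index, identity). The aligner is
    the arbiter of membership, so a correct run returns an empty list; the
    partition property (every input in exactly one cluster) is also checked.
    """
    seen: set[int] = set()
    violations: list[tuple[int, int, float]] = []
    for ci, cl in enumerate(result.clusters):
        for idx, _stored in cl.members:
            if idx in seen:
                raise AssertionError(f"record {idx} assigned to multiple clusters")
            seen.add(idx)
            if idx == cl.representative:
                continue
            res = align_affine(
                result.records[idx],
                result.records[cl.representative],
                result.config.scheme,
            )
            if not identity_check(res, result.config.s):
                violations.append((idx, ci, res.identity))
    if seen != set(range(len(result.records))):
        missing = set(range(len(result.records))) - seen
        raise AssertionError(f"records not assigned to any cluster: {sorted(missing)}")
    return violations


def with_scheme(config: ClusterConfig, **scheme_fields) -> ClusterConfig:
    """Convenience: a copy of ``config`` with scoring-scheme fields replaced."""
    return replace(config, scheme=replace(config.scheme, **scheme_fields))
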