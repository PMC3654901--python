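"""Synthetic clustered read sets with ground-truth labels.

Emulates the shape of a deduplication workload: a handful of unrelated
"seed" sequences (stand-ins for distinct source loci) each spawning a family
of error-bearing copies. Per-base substitutions and indels are position
independent — no sequencer-specific error profile, no quality model (the
pipeline ignores qualities) — so within-family identities concentrate around
1 - sub_rate - indel_rate while families stay well separated. That is
exactly the structure greedy identity clustering must recover, and the known
labels make every stage of the cascade testable without external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import lcs
from .align import ScoringScheme, align_affine
from .seqio import SequenceRecord

__all__ = ["SynthConfig", "generate_read_set", "mutate"]

_BASES = "ACGT"


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters.

    n_seeds : number of cluster seed sequences (ground-truth clusters).
    reads_per_seed : mutated copies emitted per seed (the seed itself is
        also emitted, so a cluster holds reads_per_seed + 1 records).
    read_length : seed length in bases.
    sub_rate : per-base substitution probability.
    indel_rate : per-base indel probability (half insertions, half
        deletions); expected identity to the seed is roughly
        1 - sub_rate - indel_rate.
    min_seed_divergence : rejection-sample seeds until all pairwise
        identities are <= 1 - min_seed_divergence; 0 disables the check.
    seed : RNG seed; generation is fully reproducible from it.
    """

    n_seeds: int = 20
    reads_per_seed: int = 10
    read_length: int = 150
    sub_rate: float = 0.03
    indel_rate: float = 0.005
    min_seed_divergence: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.sub_rate < 1 and 0 <= self.indel_rate < 1):
            raise ValueError("mutation rates must be in [0, 1)")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if not 0 <= self.min_seed_divergence < 1:
            raise ValueError("min_seed_divergence must be in [0, 1)")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def mutate(
    sequence: str,
    sub_rate: float,
    indel_rate: float,
    rng: np.random.Generator,
) -> str:
    """One error-bearing copy of ``sequence``.

    Per position: substitute to a uniformly chosen *different* base with
    probability sub_rate; independently, with probability indel_rate/2
    insert a uniform base before the position, or with indel_rate/2 delete
    the position.
    """
    L = len(sequence)
    subs = rng.random(L) < sub_rate
    ind = rng.random(L)
    out: list[str] = []
    for i, base in enumerate(sequence):
        if ind[i] < indel_rate / 2:  # insertion before this position
            out.append(_BASES[rng.integers(0, 4)])
        elif ind[i] < indel_rate:  # deletion of this position
            continue
        if subs[i] and base in _BASES:
            choices = _BASES.replace(base, "")
            base = choices[rng.integers(0, 3)]
        out.append(base)
    return "".join(out)


def _draw_seeds(config: SynthConfig, rng: np.random.Generator) -> list[str]:
    """Rejection-sample seeds until pairwise identities respect the cap."""
    cap = 1.0 - config.min_seed_divergence
    scheme = ScoringScheme()
    seeds: list[str] = []
    pms: list[lcs.PositionMaskSet] = []
    attempts = 0
    max_attempts = 50 * max(config.n_seeds, 1)
    while len(seeds) < config.n_seeds:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not draw {config.n_seeds} seeds with pairwise identity "
                f"<= {cap:.2f} in {max_attempts} attempts; lower n_seeds or "
                f"min_seed_divergence"
            )
        cand = _random_seq(rng, config.read_length)
        rec = SequenceRecord(f"cand{attempts}", cand)
        ok = True
        if config.min_seed_divergence > 0:
            for prev, pm in zip(seeds, pms):
                # LCS ratio bounds identity from above; align only when the
                # bound alone cannot certify the pair as divergent enough
                n = min(len(cand), len(prev))
                if lcs.llcs_bitparallel(pm, rec) / n <= cap:
                    continue
                res = align_affine(rec, SequenceRecord("p", prev), scheme)
                if res.identity > cap:
                    ok = False
                    break
        if ok:
            seeds.append(cand)
            pms.append(lcs.compute_pm(rec))
    return seeds


def generate_read_set(
    config: SynthConfig,
) -> tuple[list[SequenceRecord], list[int]]:
    """Generate records plus a ground-truth seed label per record.

    Emits each seed (record id ``seed<j>``) and ``reads_per_seed`` mutated
    copies (``read<j>_<i>``), deterministically shuffled. Labels give the
    originating seed index, aligned with the returned record order.
    """
    rng = np.random.default_rng(config.seed)
    seeds = _draw_seeds(config, rng)
    records: list[SequenceRecord] = []
    labels: list[int] = []
    for j, s in enumerate(seeds):
        records.append(SequenceRecord(f"seed{j}", s))
        labels.append(j)
        for i in range(config.reads_per_seed):
            records.append(
                SequenceRecord(
                    f"read{j}_{i}",
                    mutate(s, config.sub_rate, config.indel_rate, rng),
                )
            )
            labels.append(j)
    perm = rng.permutation(len(records))
    return [records[i] for i in perm], [labels[i] for i in perm]


def write_read_set(
    records: list[SequenceRecord],
    labels: list[int],
    fasta_path,
    labels_path,
) -> None:
    """Write the read set as FASTA plus a two-column id/label TSV."""
    with open(fasta_path, "w") as fa:
        for rec in records:
            fa.write(f">{rec.id}\n{rec.seq}\n")
    with open(labels_path, "w") as fh:
        for rec, lab in zip(records, labels):
            fh.write(f"{rec.id}\t{lab}\n")
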