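"""Sequence input/output.

Reads FASTA/FASTQ into :class:`SequenceRecord` objects (order preserved —
greedy clustering is order-dependent), normalizes bases onto the alphabet
{A, C, G, T, N}, and writes the two output files: a FASTA of cluster
representatives and a CD-HIT-compatible ``.clstr`` membership listing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterator

import numpy as np
from Bio import SeqIO

if TYPE_CHECKING:  # pragma: no cover
    from .cluster import ClusteringResult

__all__ = [
    "SequenceRecord",
    "ParseError",
    "read_sequences",
    "write_clusters",
    "parse_clstr",
]

#: Integer codes for the 2-bit-style encoding; N is the out-of-alphabet sentinel.
BASE_CODES = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

_U_TO_T = str.maketrans("Uu", "Tt")
_NON_ACGT = re.compile(r"[^ACGT]")

_ENCODE_LUT = np.full(128, 4, dtype=np.uint8)
for _b, _c in BASE_CODES.items():
    _ENCODE_LUT[ord(_b)] = _c


class ParseError(ValueError):
    """Raised when an input file cannot be parsed as the requested format."""


def normalize_seq(raw: str) -> str:
    """Normalize a base string onto {A,C,G,T,N}.

    Lowercase is uppercased, U becomes T (RNA input), and every other
    character — IUPAC ambiguity codes, gaps, stray symbols — becomes N.
    """
    s = raw.translate(_U_TO_T).upper()
    return _NON_ACGT.sub("N", s)


@dataclass
class SequenceRecord:
    """A single input read.

    Attributes
    ----------
    id : str
        Record identifier (first whitespace-delimited token of the header).
    seq : str
        Uppercase bases over {A,C,G,T,N}.
    encoded : numpy.ndarray
        uint8 codes, A=0 C=1 G=2 T=3, N=4 sentinel; same length as ``seq``.
    """

    id: str
    seq: str
    encoded: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.encoded is None:
            self.encoded = _ENCODE_LUT[
                np.frombuffer(self.seq.encode("ascii"), dtype=np.uint8)
            ]
        if len(self.encoded) != len(self.seq):
            raise ValueError("encoded length does not match sequence length")

    @property
    def length(self) -> int:
        return len(self.seq)

    def __len__(self) -> int:
        return len(self.seq)


def _detect_format(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            c = line.lstrip()[0]
            if c == ">":
                return "fasta"
            if c == "@":
                return "fastq"
            raise ParseError(
                f"{path}: cannot auto-detect format; first non-blank "
                f"character {c!r} is neither '>' (FASTA) nor '@' (FASTQ)"
            )
    return "fasta"  # empty file: arbitrary, parses to an empty list


def read_sequences(path: str | Path, format: str = "auto") -> list[SequenceRecord]:
    """Read a FASTA or FASTQ file into a list of records, preserving order.

    Parameters
    ----------
    path : path to the input file.
    format : ``"fasta"``, ``"fastq"`` or ``"auto"`` (detect by the first
        non-blank character: '>' vs '@').

    Quality strings in FASTQ input are discarded; the clustering pipeline
    never uses them. An empty file yields an empty list.
    """
    path = Path(path)
    if format == "auto":
        format = _detect_format(path)
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unknown format {format!r}")
    records: list[SequenceRecord] = []
    try:
        for rec in SeqIO.parse(str(path), format):
            records.append(SequenceRecord(rec.id, normalize_seq(str(rec.seq))))
    except ValueError as exc:
        raise ParseError(
            f"{path}: malformed {format} near record {len(records) + 1}: {exc}"
        ) from exc
    return records


def write_clusters(result: "ClusteringResult", out_prefix: str | Path) -> None:
    """Write the representative FASTA and the ``.clstr`` membership file.

    ``<out_prefix>`` receives the representatives in cluster-creation order;
    ``<out_prefix>.clstr`` follows CD-HIT's text layout::

        >Cluster 0
        0	150nt, >read7... *
        1	148nt, >read12... at +/95.00%

    The representative line ends with ``*``; member lines carry the identity
    to the representative as a percentage with two decimals.
    """
    out_prefix = Path(out_prefix)
    records = result.records
    with open(out_prefix, "w") as fa:
        for cl in result.clusters:
            rep = records[cl.representative]
            fa.write(f">{rep.id}\n{rep.seq}\n")
    with open(f"{out_prefix}.clstr", "w") as fh:
        for ci, cl in enumerate(result.clusters):
            fh.write(f">Cluster {ci}\n")
            line_no = 0
            rep = records[cl.representative]
            fh.write(f"{line_no}\t{rep.length}nt, >{rep.id}... *\n")
            for idx, ident in cl.members:
                if idx == cl.representative:
                    continue
                line_no += 1
                rec = records[idx]
                fh.write(
                    f"{line_no}\t{rec.length}nt, >{rec.id}... at +/{ident * 100:.2f}%\n"
                )


_CLSTR_LINE = re.compile(
    r"^(\d+)\t(\d+)nt, >(.*)\.\.\. (?:\*|at \+/(\d+(?:\.\d+)?)%)$"
)


def parse_clstr(path: str | Path) -> dict[str, tuple[int, bool, float]]:
    """Parse a ``.clstr`` file.

    Returns a map ``record id -> (cluster index, is_representative,
    identity)``; representatives carry identity 1.0. Used by the ``verify``
    subcommand and as the round-trip check for :func:`write_clusters`.
    """
    out: dict[str, tuple[int, bool, float]] = {}
    cluster = -1
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">Cluster"):
                cluster = int(line.split()[1])
                continue
            m = _CLSTR_LINE.match(line)
            if m is None:
                raise ParseError(f"{path}: unrecognized .clstr line {ln}: {line!r}")
            name = m.group(3)
            if m.group(4) is None:
                out[name] = (cluster, True, 1.0)
            else:
                out[name] = (cluster, False, float(m.group(4)) / 100.0)
    return out


def iter_fasta_ids(path: str | Path) -> Iterator[str]:
    """Yield record ids of a FASTA file without materializing sequences."""
    for rec in SeqIO.parse(str(Path(path)), "fasta"):
        yield rec.id
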