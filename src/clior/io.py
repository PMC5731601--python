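"""Reads, assignment tables, and their on-disk formats.

A *Read* is one sequencing read; an *AssignmentTable* maps every read of a
dataset to a taxon label at one taxonomic rank, with an explicit UNASSIGNED
state for reads the classifier left unlabeled.  Assignment files follow the
Clark CSV layout (first column read id, last column assignment, ``NA`` for
unassigned) but both the delimiter and the unassigned token are configurable.
"""

from __future__ import annotations

import csv
import gzip
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO

logger = logging.getLogger(__name__)


class _Unassigned:
    """Singleton sentinel for reads the classifier left unlabeled."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "UNASSIGNED"

    def __reduce__(self):
        return (_Unassigned, ())


#: Sentinel used in :class:`AssignmentTable` entries for unlabeled reads.
UNASSIGNED = _Unassigned()


@dataclass(frozen=True)
class Read:
    """One sequencing read: an opaque id and its nucleotide sequence."""

    read_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.read_id:
            raise ValueError("read_id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"read {self.read_id!r}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


class AssignmentTable:
    """Per-read taxon labels at one taxonomic rank.

    Parameters
    ----------
    rank
        Taxonomic rank name, e.g. ``"species"`` or ``"genus"``.
    entries
        Mapping read id -> taxon label (opaque non-empty string) or
        :data:`UNASSIGNED`.
    """

    def __init__(self, rank: str, entries: Mapping[str, object] | None = None):
        self.rank = rank
        self.entries: dict[str, object] = {}
        if entries:
            for rid, label in entries.items():
                self[rid] = label

    def __setitem__(self, read_id: str, label: object) -> None:
        if label is not UNASSIGNED and (not isinstance(label, str) or not label):
            raise ValueError(f"taxon label for {read_id!r} must be a non-empty string or UNASSIGNED")
        self.entries[read_id] = label

    def __getitem__(self, read_id: str) -> object:
        return self.entries[read_id]

    def __contains__(self, read_id: str) -> bool:
        return read_id in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AssignmentTable):
            return NotImplemented
        return self.rank == other.rank and self.entries == other.entries

    def __repr__(self) -> str:
        n_lab = sum(1 for v in self.entries.values() if v is not UNASSIGNED)
        return f"AssignmentTable(rank={self.rank!r}, n={len(self)}, labeled={n_lab})"

    def labels(self) -> set[str]:
        """Distinct non-UNASSIGNED labels present in the table."""
        return {v for v in self.entries.values() if v is not UNASSIGNED}

    def n_assigned(self) -> int:
        return sum(1 for v in self.entries.values() if v is not UNASSIGNED)

    def copy(self) -> "AssignmentTable":
        return AssignmentTable(self.rank, dict(self.entries))


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _sniff_format(path: Path) -> str:
    name = path.name[:-3] if path.name.endswith(".gz") else path.name
    suffix = Path(name).suffix.lower()
    if suffix in {".fa", ".fasta", ".fna"}:
        return "fasta"
    if suffix in {".fq", ".fastq"}:
        return "fastq"
    raise ValueError(f"cannot infer read format from file name {path.name!r}; pass format=")


def read_sequences(
    path: str | Path,
    format: str | None = None,
    mate_path: str | Path | None = None,
) -> list[Read]:
    """Load reads from FASTA/FASTQ (optionally gzipped).

    The returned order is the file order and defines the canonical read
    index ``0..N-1`` used by the overlap graph.  With ``mate_path`` given,
    the two files are treated as a read pair: mates are interleaved so that
    record ``i`` of each file yields adjacent reads.  Mates are kept as
    independent reads (each is classified and voted on individually); the
    pairing survives only in the read-id suffixes.
    """
    path = Path(path)
    fmt = format or _sniff_format(path)
    if mate_path is not None:
        first = _parse_records(path, fmt)
        second = _parse_records(Path(mate_path), format or _sniff_format(Path(mate_path)))
        reads: list[Read] = []
        for r1, r2 in zip(first, second, strict=True):
            reads.append(r1)
            reads.append(r2)
    else:
        reads = list(_parse_records(path, fmt))
    seen: set[str] = set()
    for r in reads:
        if r.read_id in seen:
            raise ValueError(f"duplicate read id {r.read_id!r}")
        seen.add(r.read_id)
    return reads


def _parse_records(path: Path, fmt: str) -> Iterator[Read]:
    if fmt not in {"fasta", "fastq"}:
        raise ValueError(f"unsupported read format {fmt!r}")
    with _open_text(path) as handle:
        try:
            for rec in SeqIO.parse(handle, fmt):
                yield Read(rec.id, str(rec.seq).upper())
        except ValueError as exc:
            raise ValueError(f"malformed {fmt} record in {path}: {exc}") from exc


def write_sequences(reads: Iterable[Read], path: str | Path, format: str | None = None) -> None:
    """Write reads as FASTA or FASTQ (constant placeholder qualities)."""
    path = Path(path)
    fmt = format or _sniff_format(path)
    with _open_text(path, "wt") as out:
        for r in reads:
            if fmt == "fasta":
                out.write(f">{r.read_id}\n{r.sequence}\n")
            else:
                out.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * r.length}\n")


def read_assignments(
    path: str | Path,
    rank: str = "species",
    unassigned_token: str = "NA",
    delimiter: str | None = None,
    known_reads: Iterable[str] | None = None,
    on_unknown: str = "error",
) -> AssignmentTable:
    """Parse a Clark-style assignment table.

    The first column is the read id and the last column the assignment;
    intermediate columns (hit counts, confidence, ...) are ignored.  The
    first line is skipped when its first cell looks like a header name
    (``Object_ID``, ``read_id``, ...); the delimiter (comma or tab) is
    sniffed from the first line unless given.

    Parameters
    ----------
    on_unknown
        What to do with rows whose read id is not in ``known_reads`` (when
        given): ``"error"`` or ``"skip"`` (warn and drop).
    """
    path = Path(path)
    known = set(known_reads) if known_reads is not None else None
    table = AssignmentTable(rank)
    with _open_text(path) as handle:
        text = handle.read()
    if not text.strip():
        warnings.warn(f"{path}: empty assignment file", stacklevel=2)
        return table
    if delimiter is None:
        first_line = text.splitlines()[0]
        delimiter = "\t" if first_line.count("\t") >= first_line.count(",") and "\t" in first_line else ","
    rows = list(csv.reader(text.splitlines(), delimiter=delimiter))
    start = 0
    if rows and rows[0] and _looks_like_header(rows[0]):
        start = 1
    for lineno, row in enumerate(rows[start:], start=start + 1):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) < 2:
            raise ValueError(f"{path}:{lineno}: expected >=2 columns, got {row!r}")
        rid, label = row[0].strip(), row[-1].strip()
        if known is not None and rid not in known:
            if on_unknown == "skip":
                logger.warning("%s:%d: unknown read id %r skipped", path, lineno, rid)
                continue
            raise ValueError(f"{path}:{lineno}: read id {rid!r} absent from the read set")
        if rid in table:
            raise ValueError(f"{path}:{lineno}: duplicate assignment for read {rid!r}")
        table[rid] = UNASSIGNED if label == unassigned_token else label
    return table


def _looks_like_header(row: list[str]) -> bool:
    head = row[0].strip().lower()
    return head in {"object_id", "read_id", "readid", "id", "read", "#read_id"}


def write_assignments(
    table: AssignmentTable,
    path: str | Path,
    unassigned_token: str = "NA",
    delimiter: str = ",",
    header: bool = True,
) -> None:
    """Write an assignment table; round-trips through :func:`read_assignments`."""
    path = Path(path)
    with _open_text(path, "wt") as out:
        if header:
            out.write(f"read_id{delimiter}assignment\n")
        for rid in sorted(table.entries):
            label = table.entries[rid]
            token = unassigned_token if label is UNASSIGNED else label
            out.write(f"{rid}{delimiter}{token}\n")
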