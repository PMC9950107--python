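"""Readers and writers for the external formats the pipeline touches.

Every other module operates on the in-memory domain types defined here:
:class:`SequenceRecord` collections (from FASTA), :class:`InteractionList`
(two-column TSV of known lncRNA-protein pairs), :class:`BlastHitTable`
(12-column BLAST tabular output), and :class:`EmbeddingTable` (plain-text
whitespace-delimited vectors with a dimension header).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGTUN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class FormatError(ValueError):
    """Base class for all file-format violations raised by this module."""


class MissingFileError(FormatError):
    pass


class EmptyFileError(FormatError):
    pass


class DuplicateIdError(FormatError):
    pass


class AlphabetError(FormatError):
    pass


class LineParseError(FormatError):
    """Malformed line; carries the 1-based line number in ``lineno``."""

    def __init__(self, message: str, lineno: int):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


class DimensionError(FormatError):
    pass


class EmptyTableError(FormatError):
    pass


class MolType(Enum):
    RNA = "RNA"
    PROTEIN = "PROTEIN"


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide or amino-acid sequence.

    RNA sequences may use either U or T (public lncRNA FASTA files use both
    conventions); protein sequences use the 20 standard letters plus X.
    """

    id: str
    seq: str
    moltype: MolType

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.seq:
            raise AlphabetError(f"record {self.id!r}: empty sequence")
        alphabet = RNA_ALPHABET if self.moltype is MolType.RNA else PROTEIN_ALPHABET
        bad = set(self.seq) - alphabet
        if bad:
            raise AlphabetError(
                f"record {self.id!r}: characters {sorted(bad)} not allowed "
                f"for moltype {self.moltype.value}"
            )


@dataclass(frozen=True)
class InteractionList:
    """Deduplicated set of known (lncRNA id, protein id) pairs."""

    pairs: frozenset[tuple[str, str]]

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.pairs

    def lncrna_ids(self) -> set[str]:
        return {l for l, _ in self.pairs}

    def protein_ids(self) -> set[str]:
        return {p for _, p in self.pairs}


@dataclass
class BlastHitTable:
    """Per-pair minimum e-value and bitscore from tabular BLAST output.

    Self-hits are dropped on construction; multiple HSPs for the same
    (query, subject) pair are collapsed to the minimum e-value, since the
    downstream edge filter thresholds a single scalar per pair.
    """

    hits: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)

    def add(self, query: str, subject: str, evalue: float, bitscore: float) -> None:
        if query == subject:
            return
        if evalue < 0:
            raise ValueError(f"negative e-value for ({query}, {subject})")
        key = (query, subject)
        if key not in self.hits or evalue < self.hits[key][0]:
            self.hits[key] = (evalue, bitscore)

    def evalue(self, a: str, b: str) -> float | None:
        """Best (minimum) e-value over both orientations, or None if no hit."""
        candidates = [self.hits[k][0] for k in ((a, b), (b, a)) if k in self.hits]
        return min(candidates) if candidates else None

    def __len__(self) -> int:
        return len(self.hits)


@dataclass
class EmbeddingTable:
    """Ordered id -> latent-vector map; the on-disk format is one header
    line holding the dimension, then ``id v1 v2 ... vd`` per row."""

    ids: list[str]
    vectors: np.ndarray  # shape (len(ids), d)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.ids):
            raise DimensionError("vectors must be 2-D with one row per id")
        if len(set(self.ids)) != len(self.ids):
            raise DuplicateIdError("duplicate ids in embedding table")
        self._index = {i: k for k, i in enumerate(self.ids)}

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def vector(self, node_id: str) -> np.ndarray:
        return self.vectors[self._index[node_id]]

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._index

    def __len__(self) -> int:
        return len(self.ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EmbeddingTable):
            return NotImplemented
        return self.ids == other.ids and np.array_equal(self.vectors, other.vectors)


def read_fasta(path: str | Path, moltype: MolType) -> list[SequenceRecord]:
    """Parse a FASTA file into :class:`SequenceRecord` objects.

    Sequences are uppercased; wrapped sequence lines are concatenated.
    Raises :class:`MissingFileError`, :class:`EmptyFileError`,
    :class:`DuplicateIdError` or :class:`AlphabetError` as appropriate.
    """
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"no such file: {path}")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq).upper(), moltype))
    if not records:
        raise EmptyFileError(f"no FASTA records in {path}")
    return records


def read_interactions(path: str | Path) -> InteractionList:
    """Read a two-column (lncRNA id, protein id) interaction file.

    Duplicate pairs are dropped with a logged count; a line without exactly
    two whitespace-separated columns raises :class:`LineParseError`.
    """
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"no such file: {path}")
    pairs: set[tuple[str, str]] = set()
    duplicates = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 2:
                raise LineParseError(
                    f"expected 2 columns, got {len(fields)}", lineno
                )
            pair = (fields[0], fields[1])
            if pair in pairs:
                duplicates += 1
            else:
                pairs.add(pair)
    if duplicates:
        logger.info("read_interactions: dropped %d duplicate pairs", duplicates)
    return InteractionList(frozenset(pairs))


def read_blast_tab(path: str | Path) -> BlastHitTable:
    """Read 12-column tabular BLAST output (outfmt-6 dialect).

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore; extra trailing columns are ignored.
    Self-hits are discarded; the minimum e-value per pair is retained.
    """
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"no such file: {path}")
    table = BlastHitTable()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise LineParseError(
                    f"expected >= 12 tab-separated columns, got {len(fields)}",
                    lineno,
                )
            try:
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise LineParseError(f"non-numeric e-value/bitscore: {exc}", lineno)
            table.add(fields[0], fields[1], evalue, bitscore)
    return table


def write_embeddings(table: EmbeddingTable, path: str | Path) -> None:
    """Write an embedding table; round-trips exactly through
    :func:`read_embeddings` (ids verbatim, values at full float precision)."""
    if len(table) == 0:
        raise EmptyTableError("refusing to write an empty embedding table")
    with open(path, "w") as fh:
        fh.write(f"{table.dim}\n")
        for node_id, row in zip(table.ids, table.vectors):
            vals = " ".join(repr(float(v)) for v in row)
            fh.write(f"{node_id} {vals}\n")


def read_embeddings(path: str | Path) -> EmbeddingTable:
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"no such file: {path}")
    with open(path) as fh:
        header = fh.readline().strip()
        try:
            dim = int(header)
        except ValueError:
            raise DimensionError(f"bad dimension header {header!r}")
        ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != dim + 1:
                raise DimensionError(
                    f"line {lineno}: expected {dim} values, got {len(fields) - 1}"
                )
            ids.append(fields[0])
            rows.append([float(v) for v in fields[1:]])
    if not ids:
        raise EmptyTableError(f"no embedding rows in {path}")
    return EmbeddingTable(ids, np.array(rows))


def check_unique_ids(records: Iterable[SequenceRecord]) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
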