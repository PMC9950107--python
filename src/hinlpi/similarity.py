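"""Alignment-free sequence similarity and BLAST-evidence normalization.

Two similarity channels feed the heterogeneous network: the Jaccard index
between k-mer sets (a sequence is represented as its set of length-k
substrings, so |A∩B| / |A∪B| measures shared composition independent of
alignment), and a per-pair scalar e-value taken from a BLAST tabular file.

For test and demonstration runs with no external aligner available, a small
Smith-Waterman scorer with *fixed, fake* Karlin-Altschul constants maps the
local-alignment score S to a deterministic pseudo-e-value K·m·n·exp(-λS).
It is a stand-in with the right monotonicity (more similar -> smaller value),
not a reproduction of real BLAST statistics.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from Bio import Align

from .io_formats import BlastHitTable, MolType, SequenceRecord, check_unique_ids

DEFAULT_K_RNA = 4
DEFAULT_K_PROTEIN = 3

# fixed pseudo Karlin-Altschul constants for the toy aligner
TOY_K = 0.1
TOY_LAMBDA = 0.7


@dataclass(frozen=True)
class KmerSet:
    """The set of distinct length-k substrings of one sequence."""

    owner: str
    k: int
    members: frozenset[str]


@dataclass
class SimilarityTable:
    """Symmetric per-pair (jaccard, optional blast e-value) map for one
    node type (L or P). Keys are sorted id pairs; no self pairs."""

    node_type: str  # "L" or "P"
    entries: dict[tuple[str, str], tuple[float, float | None]] = field(
        default_factory=dict
    )

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        if a == b:
            raise ValueError(f"self pair {a!r}")
        return (a, b) if a < b else (b, a)

    def set(self, a: str, b: str, jaccard: float, evalue: float | None) -> None:
        self.entries[self._key(a, b)] = (jaccard, evalue)

    def get(self, a: str, b: str) -> tuple[float, float | None]:
        return self.entries[self._key(a, b)]

    def __len__(self) -> int:
        return len(self.entries)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for (a, b), (j, e) in sorted(self.entries.items()):
                ev = "NA" if e is None else repr(e)
                fh.write(f"{a}\t{b}\t{j!r}\t{ev}\n")


def kmerize(record: SequenceRecord, k: int) -> KmerSet:
    """All distinct length-k windows of the sequence (stride 1)."""
    if k < 1:
        raise ValueError("k must be positive")
    if len(record.seq) < k:
        raise ValueError(
            f"sequence {record.id!r} shorter than k={k} ({len(record.seq)} chars)"
        )
    seq = record.seq
    members = frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))
    return KmerSet(record.id, k, members)


def jaccard(a: KmerSet, b: KmerSet) -> float:
    """|A∩B| / |A∪B| on the two k-mer sets; requires matching k."""
    if a.k != b.k:
        raise ValueError(f"mismatched k: {a.k} vs {b.k}")
    if not a.members or not b.members:
        raise ValueError("empty k-mer set")
    inter = len(a.members & b.members)
    union = len(a.members | b.members)
    return inter / union


def default_k(moltype: MolType) -> int:
    return DEFAULT_K_RNA if moltype is MolType.RNA else DEFAULT_K_PROTEIN


def pairwise_similarity(
    records: Sequence[SequenceRecord],
    k: int | None = None,
    blast: BlastHitTable | None = None,
) -> SimilarityTable:
    """Jaccard for every unordered pair, with the pair's minimum BLAST
    e-value attached where the hit table has one (None otherwise: a pair
    with no hit carries no BLAST evidence, which is *not* e-value 0)."""
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    moltypes = {r.moltype for r in records}
    if len(moltypes) > 1:
        raise ValueError("mixed moltypes in one similarity computation")
    moltype = moltypes.pop()
    check_unique_ids(records)
    if k is None:
        k = default_k(moltype)
    node_type = "L" if moltype is MolType.RNA else "P"
    table = SimilarityTable(node_type)
    ksets = {r.id: kmerize(r, k) for r in records}
    for ra, rb in itertools.combinations(records, 2):
        j = jaccard(ksets[ra.id], ksets[rb.id])
        ev = blast.evalue(ra.id, rb.id) if blast is not None else None
        table.set(ra.id, rb.id, j, ev)
    return table


def _aligner(moltype: MolType) -> Align.PairwiseAligner:
    # identity scoring for both alphabets: match +1, mismatch -1, linear gap -2
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


def toy_local_align_evalue(a: SequenceRecord, b: SequenceRecord) -> float:
    """Deterministic pseudo-e-value K·m·n·exp(-λS) from the Smith-Waterman
    score S under fixed scoring (+1 match, -1 mismatch, -2 linear gap) and
    fixed fake constants K=0.1, λ=0.7. Symmetric in its arguments."""
    if a.moltype is not b.moltype:
        raise ValueError("moltype mismatch")
    if not a.seq or not b.seq:
        raise ValueError("empty sequence")
    score = _aligner(a.moltype).score(a.seq, b.seq)
    score = max(score, 0.0)
    return TOY_K * len(a.seq) * len(b.seq) * math.exp(-TOY_LAMBDA * score)


def toy_blast_table(records: Sequence[SequenceRecord]) -> BlastHitTable:
    """All-vs-all pseudo-e-values from :func:`toy_local_align_evalue`,
    packaged like a parsed BLAST tabular file so the rest of the pipeline
    is agnostic to where its e-values came from."""
    table = BlastHitTable()
    for ra, rb in itertools.combinations(records, 2):
        ev = toy_local_align_evalue(ra, rb)
        table.add(ra.id, rb.id, ev, 0.0)
    return table
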