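"""Synthetic data with planted community structure.

Two generators emulate what the real pipeline consumes:

* :func:`synth_sequences` — per community, one random ancestor lncRNA and
  one ancestor protein; members are per-site mutated copies, so
  within-community k-mer Jaccard (and local-alignment score) exceeds the
  between-community value in expectation.
* :func:`synth_network` — a stochastic-block-model heterogeneous network:
  similarity edges within a node type with probability p_within (same
  community) or p_between (different), and lncRNA-protein interactions
  drawn with the same block bias.

Both are pure functions of their seed. Ground-truth community labels are
returned so downstream tests can assert structure recovery.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .hetnet import HeteroNetwork, build_network
from .io_formats import InteractionList, MolType, SequenceRecord

RNA_LETTERS = "ACGU"
PROTEIN_LETTERS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the planted-structure generator.

    Defaults: 40 lncRNAs and 20 proteins in 4 communities; dense
    within-community structure (p_within=0.5) against sparse background
    (p_between=0.05); sequences of 150-250 letters with a 2% per-site
    mutation rate off the community ancestor, enough divergence to be
    realistic while keeping within-community Jaccard clearly above the
    between-community level.
    """

    n_lncrna: int = 40
    n_protein: int = 20
    n_communities: int = 4
    p_within: float = 0.5
    p_between: float = 0.05
    seq_length: tuple[int, int] = (150, 250)
    mutation_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_between < self.p_within <= 1:
            raise ValueError("need 0 <= p_between < p_within <= 1")
        if min(self.n_lncrna, self.n_protein, self.n_communities) < 1:
            raise ValueError("counts must be >= 1")
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation rate in [0,1]")


def _community_of(index: int, total: int, n_comm: int) -> int:
    # contiguous blocks, first communities one larger when uneven
    base, extra = divmod(total, n_comm)
    bound = 0
    for c in range(n_comm):
        bound += base + (1 if c < extra else 0)
        if index < bound:
            return c
    raise AssertionError


def community_labels(config: SynthConfig) -> dict[str, int]:
    labels = {}
    for i in range(config.n_lncrna):
        labels[f"L{i + 1}"] = _community_of(i, config.n_lncrna, config.n_communities)
    for i in range(config.n_protein):
        labels[f"P{i + 1}"] = _community_of(i, config.n_protein, config.n_communities)
    return labels


def _mutate(seq: str, rate: float, letters: str, rng: np.random.Generator) -> str:
    if rate == 0:
        return seq
    chars = list(seq)
    hits = rng.random(len(chars)) < rate
    for i in np.flatnonzero(hits):
        chars[i] = letters[rng.integers(len(letters))]  # uniform resampling
    return "".join(chars)


def synth_sequences(
    config: SynthConfig,
) -> tuple[list[SequenceRecord], list[SequenceRecord], dict[str, int]]:
    """Community-structured lncRNA and protein sequence sets plus the
    ground-truth community label of every id."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.seq_length
    ancestors_rna = []
    ancestors_prot = []
    for _ in range(config.n_communities):
        ln = int(rng.integers(lo, hi + 1))
        ancestors_rna.append(
            "".join(RNA_LETTERS[i] for i in rng.integers(0, 4, ln))
        )
        lp = int(rng.integers(lo, hi + 1))
        ancestors_prot.append(
            "".join(PROTEIN_LETTERS[i] for i in rng.integers(0, 20, lp))
        )
    labels = community_labels(config)
    lnc = [
        SequenceRecord(
            f"L{i + 1}",
            _mutate(ancestors_rna[labels[f"L{i + 1}"]], config.mutation_rate,
                    RNA_LETTERS, rng),
            MolType.RNA,
        )
        for i in range(config.n_lncrna)
    ]
    prot = [
        SequenceRecord(
            f"P{i + 1}",
            _mutate(ancestors_prot[labels[f"P{i + 1}"]], config.mutation_rate,
                    PROTEIN_LETTERS, rng),
            MolType.PROTEIN,
        )
        for i in range(config.n_protein)
    ]
    return lnc, prot, labels


def synth_interactions(
    config: SynthConfig, seed_offset: int = 1
) -> InteractionList:
    """Block-biased known-interaction list: (L, P) pairs interact with
    probability p_within inside a community, p_between across."""
    rng = np.random.default_rng(config.seed + seed_offset)
    labels = community_labels(config)
    pairs = set()
    for i in range(config.n_lncrna):
        for j in range(config.n_protein):
            l, p = f"L{i + 1}", f"P{j + 1}"
            prob = config.p_within if labels[l] == labels[p] else config.p_between
            if rng.random() < prob:
                pairs.add((l, p))
    return InteractionList(frozenset(pairs))


def synth_network(
    config: SynthConfig,
) -> tuple[HeteroNetwork, InteractionList, dict[str, int]]:
    """Stochastic-block heterogeneous network with planted communities;
    returns the network, the planted interactions and the labels."""
    rng = np.random.default_rng(config.seed + 2)
    labels = community_labels(config)
    l_ids = [f"L{i + 1}" for i in range(config.n_lncrna)]
    p_ids = [f"P{i + 1}" for i in range(config.n_protein)]

    def block_edges(ids: list[str]) -> set[tuple[str, str]]:
        edges = set()
        for a_i in range(len(ids)):
            for b_i in range(a_i + 1, len(ids)):
                a, b = ids[a_i], ids[b_i]
                prob = (
                    config.p_within
                    if labels[a] == labels[b]
                    else config.p_between
                )
                if rng.random() < prob:
                    edges.add((a, b))
        return edges

    l_edges = block_edges(l_ids)
    p_edges = block_edges(p_ids)
    interactions = synth_interactions(config)
    net, _ = build_network(l_edges, p_edges, interactions, l_ids, p_ids)
    return net, interactions, labels


def write_synth_dataset(config: SynthConfig, out_dir: str | Path) -> None:
    """FASTA x2 + interactions TSV + ground-truth labels TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lnc, prot, labels = synth_sequences(config)
    with open(out / "lncrna.fasta", "w") as fh:
        for rec in lnc:
            fh.write(f">{rec.id}\n{rec.seq}\n")
    with open(out / "protein.fasta", "w") as fh:
        for rec in prot:
            fh.write(f">{rec.id}\n{rec.seq}\n")
    interactions = synth_interactions(config)
    with open(out / "interactions.tsv", "w") as fh:
        for l, p in sorted(interactions.pairs):
            fh.write(f"{l}\t{p}\n")
    with open(out / "communities.tsv", "w") as fh:
        for node, c in sorted(labels.items()):
            fh.write(f"{node}\t{c}\n")
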