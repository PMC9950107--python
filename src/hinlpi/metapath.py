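"""Meta-path relation enumeration and training-data preparation.

A *relation* is a node-type pattern such as L-P or L-L-P. The relation set R
collects every pattern of 1..max_len edges whose single-step transitions are
realizable in the network at hand (no P-P patterns if no protein-protein
edges exist), in canonical order: ascending length, then lexicographic with
L < P. That order fixes the one-hot index map: in the two-type setting with
L-L and L-P edges and max_len=2 it yields exactly

    L-L, L-P, P-L, L-L-L, L-L-P, L-P-L, P-L-L, P-L-P.

Training tuples come from uniform-neighbor random walks: every ordered node
pair within max_len steps along a walk becomes a positive example labeled
with *all* relations that hold between the two nodes (any-path semantics,
matching the worked example in which L1 -> P1 is labeled with both L-P and
L-L-P). Negatives keep the source node and one sampled relation but replace
the target with a random same-type node for which that relation does not
hold.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .hetnet import HeteroNetwork

Relation = tuple[str, ...]  # node-type pattern, e.g. ("L", "L", "P")


def format_relation(rel: Relation) -> str:
    return "-".join(rel)


@dataclass(frozen=True)
class RelationSet:
    """Ordered, indexed collection of distinct relations."""

    relations: tuple[Relation, ...]

    def __post_init__(self) -> None:
        if len(set(self.relations)) != len(self.relations):
            raise ValueError("duplicate relations")

    def __len__(self) -> int:
        return len(self.relations)

    def __iter__(self):
        return iter(self.relations)

    def __getitem__(self, i: int) -> Relation:
        return self.relations[i]

    def index(self, rel: Relation) -> int:
        return self.relations.index(rel)

    def as_strings(self) -> list[str]:
        return [format_relation(r) for r in self.relations]


@dataclass(frozen=True)
class TrainingTuple:
    """(source m, target n, relation indicator y over R, binary label).

    Positives carry a multi-hot y (>= 1 set bit: every relation holding
    between m and n); negatives carry exactly one set bit, the sampled
    relation that does *not* hold.
    """

    m: str
    n: str
    y: tuple[int, ...]
    label: int

    @property
    def relation_indices(self) -> tuple[int, ...]:
        return tuple(i for i, bit in enumerate(self.y) if bit)


def enumerate_relations(
    types: Sequence[str] = ("L", "P"),
    max_len: int = 2,
    allowed_edge_types: Iterable[tuple[str, str]] | None = None,
) -> RelationSet:
    """All type patterns of 1..max_len edges whose consecutive steps are
    realizable edges, ordered by length then lexicographically.

    ``allowed_edge_types`` holds unordered type pairs as sorted tuples,
    e.g. {("L", "L"), ("L", "P")} for a network with no protein-protein
    edges; by default every pair of the given types is allowed.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    types = sorted(types)
    if allowed_edge_types is None:
        allowed = {
            tuple(sorted((a, b))) for a in types for b in types
        }
    else:
        allowed = {tuple(sorted(p)) for p in allowed_edge_types}
    out: list[Relation] = []
    for n_edges in range(1, max_len + 1):
        patterns = [(t,) for t in types]
        for _ in range(n_edges):
            patterns = [
                p + (t,)
                for p in patterns
                for t in types
                if tuple(sorted((p[-1], t))) in allowed
            ]
        out.extend(sorted(patterns))
    return RelationSet(tuple(out))


def _paths_type_patterns(
    network: HeteroNetwork, m: str, n: str, max_len: int
) -> set[Relation]:
    """Type patterns of all simple paths m -> n of <= max_len edges.

    Intermediate nodes are distinct and exclude the endpoints; when m == n
    the patterns are those of short cycles through m (none exist in a
    simple graph for max_len <= 2 unless a multi-edge would be needed).
    """
    patterns: set[Relation] = set()
    start_type = network.node_type(m)
    network.node_type(n)  # raises on unknown id

    def dfs(
        node: str,
        visited: set[str],
        used_edges: frozenset[frozenset[str]],
        pattern: tuple[str, ...],
    ) -> None:
        edges_so_far = len(pattern) - 1
        if edges_so_far >= max_len:
            return
        for nb in network.neighbors(node):
            edge = frozenset((node, nb))
            if edge in used_edges:
                # relevant only when m == n: a closed walk reusing an
                # undirected edge is not a cycle
                continue
            if nb == n:
                patterns.add(pattern + (network.node_type(nb),))
            elif nb not in visited and edges_so_far + 1 < max_len:
                dfs(
                    nb,
                    visited | {nb},
                    used_edges | {edge},
                    pattern + (network.node_type(nb),),
                )

    dfs(m, {m}, frozenset(), (start_type,))
    return patterns


def relation_label_vector(
    network: HeteroNetwork,
    m: str,
    n: str,
    relation_set: RelationSet,
    max_len: int = 2,
) -> tuple[int, ...]:
    """Binary indicator over R: bit i is set iff some simple path from m
    to n of at most max_len edges matches pattern R[i]."""
    patterns = _paths_type_patterns(network, m, n, max_len)
    return tuple(1 if rel in patterns else 0 for rel in relation_set)


def random_walks(
    network: HeteroNetwork,
    walks_per_node: int = 10,
    walk_length: int = 80,
    seed: int = 0,
) -> list[list[str]]:
    """Uniform-neighbor random walks of ``walk_length`` nodes, started
    ``walks_per_node`` times from every non-isolated node; reproducible
    under a fixed seed. Isolated nodes emit no walks; a dead end (never
    reached in an undirected graph once a step is taken) truncates."""
    if walk_length < 2:
        raise ValueError("walk_length must be >= 2")
    rng = np.random.default_rng(seed)
    neighbors = {v: network.neighbors(v) for v in network.nodes()}
    walks: list[list[str]] = []
    for start in network.nodes():
        if not neighbors[start]:
            continue
        for _ in range(walks_per_node):
            walk = [start]
            while len(walk) < walk_length:
                nbs = neighbors[walk[-1]]
                if not nbs:
                    break
                walk.append(nbs[rng.integers(len(nbs))])
            walks.append(walk)
    return walks


def walks_to_tuples(
    walks: Sequence[Sequence[str]],
    network: HeteroNetwork,
    relation_set: RelationSet,
    max_len: int = 2,
    neg_per_pos: int = 5,
    seed: int = 0,
    _max_resample: int = 50,
) -> list[TrainingTuple]:
    """Positive tuples from every ordered pair within a max_len-edge walk
    window, plus ``neg_per_pos`` sampled negatives per positive.

    A window pair whose relation vector is all-zero (e.g. the walk doubled
    back, so m == n without a short cycle) emits nothing. Each negative
    draws one of the positive's relations uniformly, then a replacement
    target of the same node type for which the relation does not hold;
    the draw is retried a bounded number of times and skipped on failure.
    """
    rng = np.random.default_rng(seed)
    label_cache: dict[tuple[str, str], tuple[int, ...]] = {}

    def label(m: str, n: str) -> tuple[int, ...]:
        key = (m, n)
        if key not in label_cache:
            label_cache[key] = relation_label_vector(
                network, m, n, relation_set, max_len
            )
        return label_cache[key]

    nodes_by_type = {t: network.nodes(t) for t in ("L", "P")}
    n_rel = len(relation_set)
    tuples: list[TrainingTuple] = []
    for walk in walks:
        for i in range(len(walk)):
            for dist in range(1, max_len + 1):
                j = i + dist
                if j >= len(walk):
                    break
                # ordered pairs: both directions of each window co-occurrence
                for m, n in ((walk[i], walk[j]), (walk[j], walk[i])):
                    y = label(m, n)
                    if not any(y):
                        continue
                    tuples.append(TrainingTuple(m, n, y, 1))
                    pos_rels = [k for k in range(n_rel) if y[k]]
                    target_pool = nodes_by_type[network.node_type(n)]
                    for _ in range(neg_per_pos):
                        r = pos_rels[rng.integers(len(pos_rels))]
                        for _ in range(_max_resample):
                            cand = target_pool[rng.integers(len(target_pool))]
                            if not label(m, cand)[r]:
                                neg_y = tuple(
                                    1 if k == r else 0 for k in range(n_rel)
                                )
                                tuples.append(TrainingTuple(m, cand, neg_y, 0))
                                break
    return tuples


def dump_tuples(tuples: Sequence[TrainingTuple], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in tuples:
            bits = "".join(str(b) for b in t.y)
            fh.write(f"{t.m}\t{t.n}\t{bits}\t{t.label}\n")
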