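import itertools

import pytest
from hypothesis import HealthCheck, settings

from hinlpi import HeteroNetwork, enumerate_relations, toy_network

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_net():
    return toy_network()


@pytest.fixture(scope="session")
def toy_relations(toy_net):
    return enumerate_relations(("L", "P"), 2, toy_net.present_edge_types())


def build_network(node_types: dict[str, str], edges) -> HeteroNetwork:
    """Assemble a HeteroNetwork from {id: type} and an iterable of id
    pairs, inferring the edge type from the endpoint types."""
    net = HeteroNetwork()
    for node, t in node_types.items():
        net.add_node(node, t)
    etype = {("L", "L"): "LL_sim", ("P", "P"): "PP_sim", ("L", "P"): "LP_interact"}
    for a, b in edges:
        key = tuple(sorted((node_types[a], node_types[b])))
        net.add_edge(a, b, etype[key])
    return net


def oracle_path_patterns(net: HeteroNetwork, m: str, n: str, max_len: int):
    """Exhaustive path enumeration: try every ordered arrangement of
    intermediate nodes and keep type patterns of realized simple paths.
    Independent of the DFS in the library."""
    nodes = net.nodes()
    has_edge = {
        frozenset((a, b))
        for a, b, _ in net.edges()
    }
    patterns = set()
    for n_edges in range(1, max_len + 1):
        k_inter = n_edges - 1
        pool = [v for v in nodes if v not in (m, n)]
        for inter in itertools.permutations(pool, k_inter):
            path = (m, *inter, n)
            if any(
                frozenset((path[i], path[i + 1])) not in has_edge
                for i in range(n_edges)
            ):
                continue
            if m == n and n_edges == 2 and path[0] == path[-1]:
                # closed walk reusing one undirected edge is not a cycle
                if frozenset((path[0], path[1])) == frozenset((path[1], path[2])):
                    continue
            patterns.add(tuple(net.node_type(v) for v in path))
    return patterns
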