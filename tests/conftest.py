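import numpy as np
import pytest

from rgsem.graph import ReciprocalGraph


@pytest.fixture
def fig_graph():
    """Five-node reciprocal graph with a gene-layer feedback loop:
    Y1⇄Y2, X1→Y1, X2→Y2, X3→Y2 and correlated exogenous pair X2−X3."""
    return ReciprocalGraph(
        ["Y1", "Y2", "X1", "X2", "X3"],
        [("Y1", "Y2"), ("Y2", "Y1"), ("X1", "Y1"), ("X2", "Y2"), ("X3", "Y2")],
        [("X2", "X3")],
    )


def random_reciprocal_graph(rng, n_nodes, p_dir=0.15, p_und=0.15):
    """Random valid reciprocal graph: draw undirected edges first, then
    directed edges only between distinct path components."""
    nodes = [f"v{i}" for i in range(n_nodes)]
    und = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_und:
                und.append((nodes[i], nodes[j]))
    g = ReciprocalGraph(nodes, [], und)
    comp_of = {}
    for comp in g.path_components():
        for v in comp:
            comp_of[v] = comp
    dirs = []
    for i in range(n_nodes):
        for j in range(n_nodes):
            if i != j and comp_of[nodes[i]] is not comp_of[nodes[j]]:
                if rng.random() < p_dir:
                    dirs.append((nodes[i], nodes[j]))
    return ReciprocalGraph(nodes, dirs, und)


def random_dag(rng, n_nodes, p_edge=0.3):
    """Random DAG over a random topological order."""
    order = rng.permutation(n_nodes)
    nodes = [f"v{i}" for i in range(n_nodes)]
    edges = []
    for a in range(n_nodes):
        for b in range(a + 1, n_nodes):
            if rng.random() < p_edge:
                edges.append((nodes[order[a]], nodes[order[b]]))
    return ReciprocalGraph(nodes, edges, [])


def random_disjoint_sets(rng, nodes, max_c=3):
    """Random disjoint nonempty a, b and (possibly empty) c."""
    nodes = list(nodes)
    rng.shuffle(nodes)
    a = {nodes[0]}
    b = {nodes[1]}
    nc = rng.integers(0, min(max_c, len(nodes) - 2) + 1)
    c = set(nodes[2: 2 + nc])
    return a, b, c


def path_enumeration_separated(graph, a, b, c):
    """Exponential oracle for separation in an undirected graph: enumerate
    every simple path between a and b and check it meets c."""
    import networkx as nx

    gx = nx.Graph()
    gx.add_nodes_from(graph.nodes)
    gx.add_edges_from(tuple(e) for e in graph.undirected_edges)
    for s in a:
        for t in b:
            for path in nx.all_simple_paths(gx, s, t):
                if not any(v in c for v in path):
                    return False
    return True
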