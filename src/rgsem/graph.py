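"""Reciprocal graphs and their Markov-property machinery.

A *reciprocal graph* (RG) has both directed and undirected edges and may
contain cycles — including 2-cycles (feedback loops, i→j plus j→i) — subject
to a single restriction: no directed edge may join two nodes of the same
*path component* (a maximal set of nodes mutually connected by undirected
paths).  RGs strictly contain undirected graphs, DAGs, chain graphs and
directed cyclic graphs, so one separation machinery serves all of them.

Conditional independence is read off an RG through moralization: for a query
"is A independent of B given C?" one takes the minimal anterior set of
A∪B∪C (the closure under repeatedly adding boundary nodes), moralizes the
induced subgraph (complete the boundary of each path component, then drop
edge directions) and checks ordinary graph separation of A and B by C in the
resulting undirected graph.  :func:`global_markov_query` implements exactly
this; it reduces to plain separation on undirected input and to d-separation
on DAG input.

A reciprocal pair i→j, j→i is stored as two directed edges, never as an
undirected edge: path components are defined by undirected edges only, and
moralization treats the two kinds differently.
"""

from __future__ import annotations

from collections.abc import Iterable
from typing import Optional

__all__ = [
    "ReciprocalGraph",
    "UndirectedGraph",
    "path_components",
    "boundary",
    "minimal_anterior_set",
    "moralize",
    "is_separated",
    "global_markov_query",
    "read_edge_list",
    "write_edge_list",
    "to_graphml",
]


def _norm_pair(i, j) -> tuple:
    return (i, j) if i <= j else (j, i)


class ReciprocalGraph:
    """Graph with directed and undirected edges, cycles allowed.

    Parameters
    ----------
    nodes : iterable of str
        Node labels (opaque strings).  Stored sorted so all outputs are
        deterministic.
    directed_edges : iterable of (source, target) pairs
        Directed edges i→j.  Self-loops are rejected.
    undirected_edges : iterable of 2-element pairs
        Undirected edges {i, j}.

    Raises
    ------
    ValueError
        If an edge endpoint is not a node, an edge is a self-loop, or a
        directed edge joins two nodes of the same path component (the RG
        condition).
    """

    def __init__(
        self,
        nodes: Iterable[str],
        directed_edges: Iterable[tuple] = (),
        undirected_edges: Iterable[tuple] = (),
    ):
        self.nodes: tuple = tuple(sorted(dict.fromkeys(nodes)))
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate node labels")

        directed = set()
        for i, j in directed_edges:
            if i == j:
                raise ValueError(f"directed self-loop {i!r}->{j!r} is not allowed")
            for v in (i, j):
                if v not in node_set:
                    raise ValueError(f"edge endpoint {v!r} is not a node")
            directed.add((i, j))
        undirected = set()
        for e in undirected_edges:
            i, j = tuple(e)
            if i == j:
                raise ValueError(f"undirected self-edge on {i!r} is not allowed")
            for v in (i, j):
                if v not in node_set:
                    raise ValueError(f"edge endpoint {v!r} is not a node")
            undirected.add(_norm_pair(i, j))
        self.directed_edges: frozenset = frozenset(directed)
        self.undirected_edges: frozenset = frozenset(undirected)

        # adjacency caches used by every query
        self._und_nbrs: dict = {v: set() for v in self.nodes}
        for i, j in self.undirected_edges:
            self._und_nbrs[i].add(j)
            self._und_nbrs[j].add(i)
        self._preds: dict = {v: set() for v in self.nodes}
        for i, j in self.directed_edges:
            self._preds[j].add(i)

        self._component_of = {}
        for comp in self.path_components():
            for v in comp:
                self._component_of[v] = comp
        for i, j in self.directed_edges:
            if self._component_of[i] is self._component_of[j]:
                raise ValueError(
                    f"directed edge {i!r}->{j!r} joins two nodes of the same "
                    "path component, violating the reciprocal-graph condition"
                )

    # -- basic queries ---------------------------------------------------

    def path_components(self) -> list:
        """Partition of the nodes into maximal undirected-connected sets.

        Two nodes share a block iff they are joined by a path of undirected
        edges; isolated nodes (w.r.t. undirected edges) form singletons.
        Blocks are returned as frozensets, sorted by their smallest label.
        """
        seen = set()
        comps = []
        for v in self.nodes:
            if v in seen:
                continue
            block = {v}
            stack = [v]
            while stack:
                u = stack.pop()
                for w in self._und_nbrs[u]:
                    if w not in block:
                        block.add(w)
                        stack.append(w)
            seen |= block
            comps.append(frozenset(block))
        return sorted(comps, key=min)

    def _check_subset(self, a: Iterable) -> set:
        a = set(a)
        for v in a:
            if v not in self._und_nbrs:
                raise ValueError(f"unknown node label {v!r}")
        return a

    def boundary(self, a: Iterable) -> set:
        """bd(a): nodes outside ``a`` with an undirected edge to ``a`` or a
        directed edge into ``a``."""
        a = self._check_subset(a)
        out = set()
        for v in a:
            out |= self._und_nbrs[v]
            out |= self._preds[v]
        return out - a

    def minimal_anterior_set(self, a: Iterable) -> set:
        """Smallest superset of ``a`` with empty boundary (closure of ``a``
        under repeatedly adding boundary nodes)."""
        s = self._check_subset(a)
        while True:
            bd = self.boundary(s)
            if not bd:
                return s
            s |= bd

    def induced_subgraph(self, a: Iterable) -> "ReciprocalGraph":
        a = self._check_subset(a)
        return ReciprocalGraph(
            a,
            [(i, j) for i, j in self.directed_edges if i in a and j in a],
            [e for e in self.undirected_edges if set(e) <= a],
        )

    def moralize(self) -> "UndirectedGraph":
        """Moral graph: complete the boundary of each path component with
        undirected edges, then drop all edge directions."""
        edges = {frozenset(e) for e in self.undirected_edges}
        edges |= {frozenset(e) for e in self.directed_edges}
        for comp in self.path_components():
            bd = sorted(self.boundary(comp))
            for ix, u in enumerate(bd):
                for w in bd[ix + 1:]:
                    edges.add(frozenset((u, w)))
        return UndirectedGraph(self.nodes, [tuple(sorted(e)) for e in edges])

    # -- dunder conveniences ---------------------------------------------

    def __eq__(self, other):
        return (
            isinstance(other, ReciprocalGraph)
            and self.nodes == other.nodes
            and self.directed_edges == other.directed_edges
            and self.undirected_edges == other.undirected_edges
        )

    def __hash__(self):
        return hash((self.nodes, self.directed_edges, self.undirected_edges))

    def __repr__(self):
        return (
            f"{type(self).__name__}({len(self.nodes)} nodes, "
            f"{len(self.directed_edges)} directed, "
            f"{len(self.undirected_edges)} undirected)"
        )


class UndirectedGraph(ReciprocalGraph):
    """Degenerate reciprocal graph with no directed edges."""

    def __init__(self, nodes: Iterable[str], edges: Iterable[tuple] = ()):
        super().__init__(nodes, (), edges)

    @property
    def edges(self) -> frozenset:
        return self.undirected_edges

    def is_separated(self, a: Iterable, b: Iterable, c: Iterable) -> bool:
        """True iff every path between ``a`` and ``b`` meets ``c``.

        Implemented as connectivity search after deleting ``c``; the
        exponential simple-path enumeration serves only as a test oracle.
        """
        a, b, c = (self._check_subset(s) for s in (a, b, c))
        if (a & b) or (a & c) or (b & c):
            raise ValueError("a, b and c must be pairwise disjoint")
        if not a or not b:
            raise ValueError("a and b must be nonempty")
        seen = set(a)
        stack = list(a)
        while stack:
            u = stack.pop()
            for w in self._und_nbrs[u]:
                if w in c or w in seen:
                    continue
                if w in b:
                    return False
                seen.add(w)
                stack.append(w)
        return True


# -- module-level functional surface -------------------------------------


def path_components(g: ReciprocalGraph) -> list:
    return g.path_components()


def boundary(g: ReciprocalGraph, a: Iterable) -> set:
    return g.boundary(a)


def minimal_anterior_set(g: ReciprocalGraph, a: Iterable) -> set:
    return g.minimal_anterior_set(a)


def moralize(g: ReciprocalGraph) -> UndirectedGraph:
    return g.moralize()


def is_separated(u: UndirectedGraph, a, b, c) -> bool:
    return u.is_separated(a, b, c)


def global_markov_query(g: ReciprocalGraph, a, b, c) -> bool:
    """Does the graph assert Z_A ⊥ Z_B | Z_C?

    True iff ``c`` separates ``a`` from ``b`` in the moral graph of the
    subgraph induced by the minimal anterior set of a∪b∪c.  Valid for
    undirected, acyclic-directed, chain and general reciprocal input alike
    (d-separation and plain separation are the special cases).
    """
    a, b, c = set(a), set(b), set(c)
    if (a & b) or (a & c) or (b & c):
        raise ValueError("a, b and c must be pairwise disjoint")
    if not a or not b:
        raise ValueError("a and b must be nonempty")
    ant = g.minimal_anterior_set(a | b | c)
    assert (a | b | c) <= ant  # conditioning nodes are in the query set
    moral = g.induced_subgraph(ant).moralize()
    return moral.is_separated(a, b, c)


# -- exchange formats -----------------------------------------------------


def write_edge_list(g: ReciprocalGraph, path) -> None:
    """Write a 3-column TSV: source, target, type∈{directed,undirected}.

    Isolated nodes are recorded with an empty target and type ``node`` so
    the graph round-trips exactly.
    """
    touched = set()
    for i, j in g.directed_edges:
        touched |= {i, j}
    for e in g.undirected_edges:
        touched |= set(e)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\ttype\n")
        for i, j in sorted(g.directed_edges):
            fh.write(f"{i}\t{j}\tdirected\n")
        for i, j in sorted(tuple(sorted(e)) for e in g.undirected_edges):
            fh.write(f"{i}\t{j}\tundirected\n")
        for v in g.nodes:
            if v not in touched:
                fh.write(f"{v}\t\tnode\n")


def read_edge_list(path) -> ReciprocalGraph:
    nodes, directed, undirected = [], [], []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["source", "target", "type"]:
            raise ValueError(f"unrecognized edge-list header: {header!r}")
        for ln, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"line {ln}: expected 3 tab-separated fields")
            s, t, kind = parts
            if kind == "node":
                nodes.append(s)
            elif kind == "directed":
                nodes += [s, t]
                directed.append((s, t))
            elif kind == "undirected":
                nodes += [s, t]
                undirected.append((s, t))
            else:
                raise ValueError(f"line {ln}: unknown edge type {kind!r}")
    return ReciprocalGraph(nodes, directed, undirected)


def to_graphml(g: ReciprocalGraph, path) -> None:
    """Export for visualization tools; undirected edges become reciprocal
    directed pairs flagged with kind='undirected'."""
    import networkx as nx

    gx = nx.DiGraph()
    gx.add_nodes_from(g.nodes)
    for i, j in sorted(g.directed_edges):
        gx.add_edge(i, j, kind="directed")
    for e in sorted(tuple(sorted(x)) for x in g.undirected_edges):
        i, j = e
        gx.add_edge(i, j, kind="undirected")
        gx.add_edge(j, i, kind="undirected")
    nx.write_graphml(gx, path)
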