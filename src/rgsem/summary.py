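"""Posterior inclusion probabilities, edge calling and degree reporting.

The posterior probability that an edge is present, e.g.
p(a_ij ≠ 0 | X, Y, Z), is estimated by the MCMC sample average
(1/L)·Σ_l 1(a_ij^(l) ≠ 0) over the retained draws; the thresholded prior
makes excluded coefficients exactly zero, so the indicator is exact.  Edges
with PIP at or above a cutoff (default 0.5, the median-probability model)
are assembled into a typed network over 4p nodes named ``<gene>.c``
(copy number), ``<gene>.m`` (methylation), ``<gene>.g`` (gene expression)
and ``<gene>.p`` (protein), with the sign of the posterior mean of the
included coefficient attached to each edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graph import ReciprocalGraph
from .mcmc import Trace

__all__ = [
    "PosteriorNetwork",
    "pip",
    "posterior_signs",
    "call_edges",
    "degree_table",
    "write_edge_table",
    "write_sif",
    "write_degree_table",
    "network_graphml",
]

_LAYER_OF_BLOCK = {"A": "gene-gene", "C": "protein-protein", "D": "gene-protein"}


def pip(trace: Trace) -> dict:
    """PIP arrays for the A, B, C, D blocks: per-entry frequency of being
    nonzero across retained draws."""
    if trace.n_draws == 0:
        raise ValueError("empty trace")
    return {name: (getattr(trace, name) != 0).mean(axis=0)
            for name in ("A", "B", "C", "D")}


def posterior_signs(trace: Trace) -> dict:
    """Sign of the posterior mean of each coefficient over the draws where
    it is nonzero (0 where it is never included or the mean ties at 0)."""
    out = {}
    for name in ("A", "B", "C", "D"):
        draws = getattr(trace, name)
        nnz = (draws != 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            mean_nz = np.where(nnz > 0, draws.sum(axis=0) / np.maximum(nnz, 1), 0.0)
        out[name] = np.sign(mean_nz)
    return out


@dataclass
class PosteriorNetwork:
    """Called network over typed molecular nodes.

    ``edges`` is a DataFrame with columns source, target, pip, sign, layer;
    ``graph`` the corresponding :class:`ReciprocalGraph` over all 4p typed
    nodes (isolated nodes included so disconnected molecules can be
    reported);  ``pips``/``signs`` keep the full arrays.
    """

    gene_labels: list
    pips: dict
    signs: dict
    cutoff: float
    edges: pd.DataFrame
    graph: ReciprocalGraph

    @property
    def isolated_nodes(self) -> list:
        touched = set()
        for _, row in self.edges.iterrows():
            touched.update((row["source"], row["target"]))
        return [v for v in self.graph.nodes if v not in touched]


def call_edges(
    pips: dict,
    signs: dict,
    cutoff: float,
    gene_labels,
) -> PosteriorNetwork:
    """Emit a directed edge for every coefficient with PIP >= cutoff.

    B columns 2i (copy number) and 2i+1 (methylation) of row i give
    ``g.c→g.g`` and ``g.m→g.g``; A[i,j] gives ``gene_j.g→gene_i.g``;
    C[i,j] gives ``gene_j.p→gene_i.p``; D[i,j] gives ``gene_j.g→gene_i.p``.
    """
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must be in (0, 1)")
    genes = list(gene_labels)
    p = len(genes)
    rows = []

    def emit(src, dst, prob, sign, layer):
        rows.append({"source": src, "target": dst, "pip": float(prob),
                     "sign": "+" if sign > 0 else ("-" if sign < 0 else "0"),
                     "layer": layer})

    for i in range(p):
        for k, suffix, layer in ((2 * i, "c", "cis-copy-number"),
                                 (2 * i + 1, "m", "cis-methylation")):
            if pips["B"][i, k] >= cutoff:
                emit(f"{genes[i]}.{suffix}", f"{genes[i]}.g",
                     pips["B"][i, k], signs["B"][i, k], layer)
    for name, src_sfx, dst_sfx in (("A", "g", "g"), ("C", "p", "p"), ("D", "g", "p")):
        mat = pips[name]
        for i in range(p):
            for j in range(p):
                if name in ("A", "C") and i == j:
                    continue
                if mat[i, j] >= cutoff:
                    emit(f"{genes[j]}.{src_sfx}", f"{genes[i]}.{dst_sfx}",
                         mat[i, j], signs[name][i, j], _LAYER_OF_BLOCK[name])

    edges = pd.DataFrame(rows, columns=["source", "target", "pip", "sign", "layer"])
    edges = edges.sort_values(["source", "target"], kind="mergesort").reset_index(drop=True)
    nodes = [f"{g}.{s}" for g in genes for s in ("c", "m", "g", "p")]
    graph = ReciprocalGraph(nodes, list(zip(edges["source"], edges["target"])))
    return PosteriorNetwork(genes, pips, signs, cutoff, edges, graph)


def degree_table(net: PosteriorNetwork) -> pd.DataFrame:
    """(molecule, degree) for every connected molecule, degree = number of
    incident called edges (in + out), sorted by degree descending with
    deterministic tie-break by label."""
    counts: dict = {}
    for _, row in net.edges.iterrows():
        for v in (row["source"], row["target"]):
            counts[v] = counts.get(v, 0) + 1
    tab = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["molecule", "degree"],
    )
    return tab


def write_edge_table(net: PosteriorNetwork, path) -> None:
    net.edges.to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_sif(net: PosteriorNetwork, path) -> None:
    """Simple interaction format for network viewers: source, relation
    (activates/inhibits), target."""
    rel = {"+": "activates", "-": "inhibits", "0": "regulates"}
    with open(path, "w", encoding="utf-8") as fh:
        for _, row in net.edges.iterrows():
            fh.write(f"{row['source']}\t{rel[row['sign']]}\t{row['target']}\n")


def write_degree_table(net: PosteriorNetwork, path) -> None:
    degree_table(net).to_csv(path, sep="\t", index=False)


def network_graphml(net: PosteriorNetwork, path) -> None:
    """GraphML export with PIP as an edge-weight attribute."""
    import networkx as nx

    gx = nx.DiGraph()
    gx.add_nodes_from(net.graph.nodes)
    for _, row in net.edges.iterrows():
        gx.add_edge(row["source"], row["target"], weight=row["pip"],
                    sign=row["sign"], layer=row["layer"])
    nx.write_graphml(gx, path)
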