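"""Weighted residue graphs: communities by edge betweenness, maximal cliques.

Coupled residue pairs (or correlated residue motions) define an undirected
weighted graph over residues.  Two graph-theoretic summaries are used:

* **Girvan–Newman communities** — iteratively remove the edge with the
  globally highest edge betweenness, recomputing betweenness after every
  removal, and keep the partition (connected components) of maximal
  weighted modularity encountered along the removal sequence.  For
  betweenness, edge *length* is the inverse of the coupling weight
  (stronger coupling = shorter path); modularity uses the raw weights.

* **Maximal cliques** — fully mutually coupled residue sets that cannot
  be extended by any adjacent vertex; the largest ones mark residues whose
  joint substitution pattern (or joint motion) is maximally constrained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .pair_selection import PairSelection


@dataclass
class CommunityPartition:
    assignment: dict  # node -> community id (0-based, deterministic order)
    modularity: float
    removal_history: list[tuple] = field(default_factory=list)

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values())) if self.assignment else 0

    def communities(self) -> list[set]:
        out: dict[int, set] = {}
        for node, cid in self.assignment.items():
            out.setdefault(cid, set()).add(node)
        return [out[c] for c in sorted(out)]


@dataclass
class CliqueSet:
    cliques: list[frozenset]

    @property
    def maximum_size(self) -> int:
        return max((len(c) for c in self.cliques), default=0)

    def maximum_cliques(self) -> list[frozenset]:
        m = self.maximum_size
        return [c for c in self.cliques if len(c) == m]


def build_graph(sel: PairSelection, kind: str = "coupling") -> nx.Graph:
    """Weighted undirected graph: one node per residue, one edge per pair.

    Duplicate pairs keep the maximum weight.  Edge weights must be
    positive; non-positive-scored pairs are dropped.
    """
    if len(sel) == 0:
        raise ValueError("cannot build a graph from an empty pair selection")
    g = nx.Graph(kind=kind)
    for i, j, s in sel.pairs:
        if i == j:
            continue
        if s <= 0:
            continue
        if g.has_edge(i, j):
            g[i][j]["weight"] = max(g[i][j]["weight"], s)
            g[i][j]["length"] = 1.0 / g[i][j]["weight"]
        else:
            g.add_edge(i, j, weight=s, length=1.0 / s)
    return g


def _partition_of(graph: nx.Graph, nodes: list) -> dict:
    comps = sorted(nx.connected_components(graph), key=lambda c: min(c))
    assignment = {}
    for cid, comp in enumerate(comps):
        for node in comp:
            assignment[node] = cid
    # isolated nodes dropped by edge removal still belong to the partition
    for node in nodes:
        assignment.setdefault(node, max(assignment.values(), default=-1) + 1)
    return assignment


def weighted_modularity(g: nx.Graph, assignment: dict) -> float:
    """Standard Newman weighted modularity Q of a node partition."""
    comms: dict[int, set] = {}
    for node, cid in assignment.items():
        comms.setdefault(cid, set()).add(node)
    if g.number_of_edges() == 0:
        return 0.0
    return nx.community.modularity(g, list(comms.values()), weight="weight")


def girvan_newman(g: nx.Graph) -> CommunityPartition:
    """Best-modularity partition along the edge-betweenness removal sequence.

    Ties on betweenness are broken by removing the lexicographically
    smallest edge, making the whole decomposition deterministic.
    """
    nodes = sorted(g.nodes())
    if g.number_of_edges() == 0:
        return CommunityPartition(
            assignment={n: k for k, n in enumerate(nodes)}, modularity=0.0
        )
    work = g.copy()
    for u, v, d in work.edges(data=True):
        # coupling graphs carry an affinity weight: length = 1/weight;
        # correlation graphs precompute a distance in "length"
        d.setdefault("length", 1.0 / d["weight"])

    best_assignment = _partition_of(work, nodes)
    best_q = weighted_modularity(g, best_assignment)
    history: list[tuple] = []
    while work.number_of_edges() > 0:
        eb = nx.edge_betweenness_centrality(work, weight="length", normalized=False)
        max_b = max(eb.values())
        candidates = [tuple(sorted(e)) for e, b in eb.items() if b >= max_b - 1e-12]
        edge = min(candidates)
        work.remove_edge(*edge)
        history.append(edge)
        assignment = _partition_of(work, nodes)
        q = weighted_modularity(g, assignment)
        if q > best_q + 1e-12:
            best_q = q
            best_assignment = assignment
    return CommunityPartition(
        assignment=best_assignment, modularity=best_q, removal_history=history
    )


def maximal_cliques(g: nx.Graph) -> CliqueSet:
    """All maximal cliques (Bron–Kerbosch enumeration), deterministically ordered."""
    cliques = [frozenset(c) for c in nx.find_cliques(g)]
    cliques.sort(key=lambda c: (-len(c), tuple(sorted(c))))
    return CliqueSet(cliques=cliques)


def community_graph(g: nx.Graph, part: CommunityPartition) -> nx.Graph:
    """Coarse-grained graph: one node per community, summed inter-community weight."""
    cg = nx.Graph()
    sizes: dict[int, int] = {}
    for node, cid in part.assignment.items():
        sizes[cid] = sizes.get(cid, 0) + 1
    for cid, size in sorted(sizes.items()):
        cg.add_node(cid, size=size)
    for u, v, d in g.edges(data=True):
        cu, cv = part.assignment[u], part.assignment[v]
        if cu == cv:
            continue
        w = d.get("weight", 1.0)
        if cg.has_edge(cu, cv):
            cg[cu][cv]["weight"] += w
        else:
            cg.add_edge(cu, cv, weight=w)
    return cg


def write_graphml(g: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(g, str(path))


def write_edge_list(g: nx.Graph, path: str | Path, part: CommunityPartition | None = None) -> None:
    """Edge-list TSV (i, j, weight[, community_i, community_j])."""
    with open(path, "w") as fh:
        header = "i\tj\tweight"
        if part is not None:
            header += "\tcommunity_i\tcommunity_j"
        fh.write(header + "\n")
        for u, v in sorted(tuple(sorted(e)) for e in g.edges()):
            line = f"{u}\t{v}\t{g[u][v]['weight']:.6g}"
            if part is not None:
                line += f"\t{part.assignment[u]}\t{part.assignment[v]}"
            fh.write(line + "\n")
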