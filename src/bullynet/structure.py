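"""Chow-Liu tree learning from plug-in mutual information.

The tree-structured network over the discretized subscales is the
maximum-weight spanning tree of the complete graph whose edge weights
are maximum-likelihood (plug-in) estimates of pairwise mutual
information.  The spanning tree is found with Kruskal's algorithm; ties
in MI are broken by lexicographic order of the sorted variable-name
pair so the learned structure is identical across runs and platforms.
The spanning tree is invariant to the MI log base (a monotone rescaling
of all weights), so MI is computed in nats throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2


def mutual_information(counts) -> float:
    """Plug-in mutual information, in nats, of a joint count table.

    ``counts`` is an r x c nonnegative matrix of co-occurrence counts
    (any overall scale; probabilities work too).  Terms with a zero
    joint cell contribute 0, per the convention 0*log(0/q) = 0.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("counts must be a 2-D table")
    total = counts.sum()
    if total <= 0:
        raise ValueError("count table is empty")
    p = counts / total
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    outer = px @ py
    terms = p[mask] * np.log(p[mask] / outer[mask])
    # summing in sorted order makes the result exactly invariant to
    # transposition (same multiset of terms either way)
    mi = float(np.sum(np.sort(terms)))
    return max(mi, 0.0)  # clamp tiny negative rounding error


def joint_counts(table: pd.DataFrame, a: str, b: str) -> pd.DataFrame:
    """Co-occurrence counts of two categorical columns, full domains kept."""
    ct = pd.crosstab(table[a], table[b], dropna=False)
    for col in (a, b):
        if isinstance(table[col].dtype, pd.CategoricalDtype):
            cats = list(table[col].cat.categories)
            if col == a:
                ct = ct.reindex(index=cats, fill_value=0)
            else:
                ct = ct.reindex(columns=cats, fill_value=0)
    return ct


def mi_matrix(table: pd.DataFrame, variables: Sequence[str] | None = None) -> pd.DataFrame:
    """Symmetric matrix of pairwise plug-in MI (nats) over the given columns."""
    variables = list(variables) if variables is not None else list(table.columns)
    m = pd.DataFrame(0.0, index=variables, columns=variables)
    for i, a in enumerate(variables):
        for b in variables[i + 1 :]:
            mi = mutual_information(joint_counts(table, a, b).to_numpy())
            m.loc[a, b] = m.loc[b, a] = mi
    return m


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def chow_liu_tree(mi: pd.DataFrame) -> list[tuple[str, str]]:
    """Maximum-weight spanning tree over an MI matrix (Kruskal).

    Returns the undirected edge list as sorted name pairs, themselves in
    deterministic order.  Equal-weight edges are taken in lexicographic
    order of the sorted pair.
    """
    nodes = list(mi.index)
    if len(nodes) < 2:
        raise ValueError("at least 2 variables are required to learn a tree")
    candidates = sorted(
        (tuple(sorted((a, b))) for i, a in enumerate(nodes) for b in nodes[i + 1 :]),
    )
    candidates.sort(key=lambda e: -float(mi.loc[e[0], e[1]]))  # stable: ties stay lexicographic
    uf = _UnionFind(nodes)
    edges: list[tuple[str, str]] = []
    for a, b in candidates:
        if uf.union(a, b):
            edges.append((a, b))
            if len(edges) == len(nodes) - 1:
                break
    return sorted(edges)


@dataclass(frozen=True)
class TreeStructure:
    """A rooted tree: undirected edges plus a parent map oriented away
    from the root."""

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    root: str
    parent: "dict[str, str | None]"

    @property
    def directed_edges(self) -> tuple[tuple[str, str], ...]:
        return tuple(sorted((p, c) for c, p in self.parent.items() if p is not None))

    def neighbors(self, node: str) -> tuple[str, ...]:
        if node not in self.nodes:
            raise KeyError(node)
        out = [b for a, b in self.edges if a == node] + [a for a, b in self.edges if b == node]
        return tuple(sorted(out))

    def children(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(c for c, p in self.parent.items() if p == node))


def orient_tree(edges: Sequence[tuple[str, str]], root: str) -> TreeStructure:
    """Direct every edge of an undirected tree away from ``root``.

    The represented joint distribution is invariant to the root choice
    (any orientation of a tree encodes the same factorization), so
    rooting is presentation, not modeling.
    """
    edges = [tuple(sorted(e)) for e in edges]
    nodes = sorted({n for e in edges for n in e})
    if root not in nodes:
        raise ValueError(f"root {root!r} is not a node of the tree")
    adj: dict[str, list[str]] = {n: [] for n in nodes}
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    parent: dict[str, str | None] = {root: None}
    frontier = [root]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in parent:
                    parent[v] = u
                    nxt.append(v)
        frontier = nxt
    if len(parent) != len(nodes) or len(edges) != len(nodes) - 1:
        raise ValueError("edge set is not a connected tree")
    return TreeStructure(tuple(nodes), tuple(sorted(set(edges))), root, parent)


def identify_predictors(network, outcome: str, alpha: float = 0.01) -> set[str]:
    """Tree neighbors of the outcome whose association passes a G-test.

    For each neighbor the pairwise joint implied by the fitted network
    (exact for MLE CPTs) gives the plug-in MI; the G statistic 2*n*MI is
    referred to chi-square with (r-1)(c-1) df.  Raw tree adjacency would
    include noise attachments, hence the significance filter.
    """
    structure: TreeStructure = network.structure
    if outcome not in structure.nodes:
        raise KeyError(outcome)
    selected: set[str] = set()
    for nb in structure.neighbors(outcome):
        joint = network.pairwise_joint(outcome, nb)
        mi = mutual_information(joint)
        r, c = joint.shape
        g = 2.0 * network.n_fit * mi
        p = float(chi2.sf(g, df=(r - 1) * (c - 1)))
        if p <= alpha:
            selected.add(nb)
    return selected


# -- exports ------------------------------------------------------------


def to_networkx(structure: TreeStructure):
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(structure.nodes)
    g.add_edges_from(structure.directed_edges)
    return g


def write_graphml(structure: TreeStructure, path) -> None:
    import networkx as nx

    nx.write_graphml(to_networkx(structure), path)


def write_dot(structure: TreeStructure, path) -> None:
    lines = ["digraph tree {"]
    for node in structure.nodes:
        lines.append(f'  "{node}";')
    for p, c in structure.directed_edges:
        lines.append(f'  "{p}" -> "{c}";')
    lines.append("}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def mi_matrix_to_csv(mi: pd.DataFrame, path) -> None:
    mi.to_csv(path)


def mi_in_bits(mi_nats) -> float:
    return float(mi_nats) / np.log(2.0)
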