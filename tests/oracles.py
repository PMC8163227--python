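"""Independent brute-force oracles used only by the tests.

Each oracle computes its quantity from the definition, without sharing
code paths with the implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def mi_definition(counts) -> float:
    """Mutual information straight from the definition (nats)."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    mi = 0.0
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            pij = counts[i, j] / n
            if pij > 0:
                pi = counts[i, :].sum() / n
                pj = counts[:, j].sum() / n
                mi += pij * math.log(pij / (pi * pj))
    return mi


def enumerate_posterior(network, query: str, evidence: dict[str, str]) -> dict[str, float]:
    """Posterior by summing the factored joint over all full assignments."""
    nodes = list(network.structure.nodes)
    domains = {v: list(network.domains[v]) for v in nodes}
    totals = {s: 0.0 for s in domains[query]}
    for states in itertools.product(*(domains[v] for v in nodes)):
        assignment = dict(zip(nodes, states))
        if any(assignment[v] != s for v, s in evidence.items()):
            continue
        p = 1.0
        for v in nodes:
            cpt = network.cpts[v]
            j = domains[v].index(assignment[v])
            if cpt.parent is None:
                p *= cpt.table[0, j]
            else:
                i = domains[cpt.parent].index(assignment[cpt.parent])
                p *= cpt.table[i, j]
        totals[assignment[query]] += p
    z = sum(totals.values())
    if z == 0:
        raise ZeroDivisionError("evidence has probability zero")
    return {s: t / z for s, t in totals.items()}


def total_tree_weight(mi_frame, edges) -> float:
    return sum(float(mi_frame.loc[a, b]) for a, b in edges)


def all_spanning_trees_3(nodes) -> list[list[tuple[str, str]]]:
    """All 3 spanning trees on 3 labelled nodes."""
    a, b, c = nodes
    return [
        [(a, b), (b, c)],
        [(a, b), (a, c)],
        [(a, c), (b, c)],
    ]


def pair_count_u(a, b) -> float:
    """min(U_A, U_B) by explicit pair counting with half-weight ties."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    u_a = 0.0
    for x in a:
        for y in b:
            if x > y:
                u_a += 1.0
            elif x == y:
                u_a += 0.5
    return min(u_a, a.size * b.size - u_a)
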