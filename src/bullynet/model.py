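"""Tree-shaped Bayesian network: CPT estimation and exact inference.

The joint distribution factorizes as P(root) * prod_c P(c | parent(c))
over the oriented tree.  CPTs are estimated from discretized data by
(optionally Laplace-smoothed) relative frequencies; posterior queries
are answered exactly by sum-product message passing on the tree, which
for these model sizes is equivalent to variable elimination and to
brute-force enumeration of the joint.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .discretize import DiscretizationScheme, SchemaError
from .structure import TreeStructure

logger = logging.getLogger(__name__)

_ROW_TOL = 1e-12


class ImpossibleEvidenceError(ValueError):
    """The entered evidence has probability zero under the model."""


@dataclass
class ConditionalProbabilityTable:
    """P(child | parent) as a (n_parent_states x n_child_states) matrix.

    A root node has ``parent=None`` and a single-row table holding its
    marginal prior.
    """

    child: str
    parent: Optional[str]
    child_states: tuple[str, ...]
    parent_states: tuple[str, ...]  # ("",) for a root node
    table: np.ndarray

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=float)
        expected = (len(self.parent_states), len(self.child_states))
        if self.table.shape != expected:
            raise ValueError(f"CPT for {self.child!r}: shape {self.table.shape} != {expected}")
        if np.any(self.table < -_ROW_TOL) or np.any(self.table > 1 + _ROW_TOL):
            raise ValueError(f"CPT for {self.child!r}: entries outside [0, 1]")
        if not np.allclose(self.table.sum(axis=1), 1.0, atol=_ROW_TOL, rtol=0.0):
            raise ValueError(f"CPT for {self.child!r}: rows do not sum to 1")


@dataclass
class PosteriorResult:
    """Posterior (or prior, for empty evidence) over one query variable."""

    variable: str
    probabilities: dict[str, float]
    evidence: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, state: str) -> float:
        return self.probabilities[state]

    def as_series(self) -> pd.Series:
        return pd.Series(self.probabilities, name=self.variable)


Evidence = Mapping[str, str]


@dataclass
class TreeBayesianNetwork:
    """Oriented tree plus one CPT per node, with fit metadata."""

    structure: TreeStructure
    cpts: dict[str, ConditionalProbabilityTable]
    domains: dict[str, tuple[str, ...]]
    alpha_laplace: float = 0.0
    n_fit: int = 0

    def __post_init__(self) -> None:
        if set(self.cpts) != set(self.structure.nodes):
            raise ValueError("CPT set must cover exactly the node set")
        for node, cpt in self.cpts.items():
            if cpt.parent != self.structure.parent[node]:
                raise ValueError(f"CPT parent for {node!r} does not match the structure")

    # -- queries -------------------------------------------------------

    def prior_marginal(self, variable: str) -> PosteriorResult:
        return self.posterior(variable, {})

    def posterior(self, query: str, evidence: Evidence) -> PosteriorResult:
        evidence = dict(evidence)
        if query not in self.structure.nodes:
            raise KeyError(f"unknown query variable {query!r}")
        if query in evidence:
            raise ValueError(f"query variable {query!r} appears in the evidence")
        for var, state in evidence.items():
            if var not in self.structure.nodes:
                raise KeyError(f"unknown evidence variable {var!r}")
            if state not in self.domains[var]:
                raise KeyError(f"unknown state {state!r} for variable {var!r}")

        belief = self._node_potential(query, evidence)
        for nb in self.structure.neighbors(query):
            belief = belief * self._message(nb, query, evidence)
        z = belief.sum()
        if z <= 0.0:
            raise ImpossibleEvidenceError(
                f"evidence {evidence} has probability 0 under the model"
            )
        probs = belief / z
        return PosteriorResult(
            variable=query,
            probabilities={s: float(p) for s, p in zip(self.domains[query], probs)},
            evidence=evidence,
        )

    def _node_potential(self, node: str, evidence: Evidence) -> np.ndarray:
        pot = np.ones(len(self.domains[node]))
        if self.structure.parent[node] is None:
            pot = pot * self.cpts[node].table[0]
        if node in evidence:
            ind = np.zeros_like(pot)
            ind[self.domains[node].index(evidence[node])] = 1.0
            pot = pot * ind
        return pot

    def _message(self, node: str, toward: str, evidence: Evidence) -> np.ndarray:
        """Sum-product message from ``node`` to its traversal-parent ``toward``."""
        pot = self._node_potential(node, evidence)
        for nb in self.structure.neighbors(node):
            if nb != toward:
                pot = pot * self._message(nb, node, evidence)
        if self.structure.parent[node] == toward:
            # edge factor is CPT(node | toward): rows index `toward`
            return self.cpts[node].table @ pot
        # else `toward` is a child of `node`: CPT(toward | node), rows index `node`
        return pot @ self.cpts[toward].table

    def pairwise_joint(self, a: str, b: str) -> np.ndarray:
        """Joint distribution of an adjacent pair implied by the model,
        as an array indexed (a-states, b-states)."""
        if b not in self.structure.neighbors(a):
            raise ValueError(f"{a!r} and {b!r} are not adjacent in the tree")
        if self.structure.parent[b] == a:
            pa = np.array([self.prior_marginal(a)[s] for s in self.domains[a]])
            return pa[:, None] * self.cpts[b].table
        pb = np.array([self.prior_marginal(b)[s] for s in self.domains[b]])
        return (pb[:, None] * self.cpts[a].table).T

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "structure": {
                "nodes": list(self.structure.nodes),
                "edges": [list(e) for e in self.structure.edges],
                "root": self.structure.root,
            },
            "domains": {v: list(s) for v, s in self.domains.items()},
            "cpts": {
                node: {
                    "parent": cpt.parent,
                    "child_states": list(cpt.child_states),
                    "parent_states": list(cpt.parent_states),
                    "table": cpt.table.tolist(),
                }
                for node, cpt in self.cpts.items()
            },
            "alpha_laplace": self.alpha_laplace,
            "n_fit": self.n_fit,
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "TreeBayesianNetwork":
        from .structure import orient_tree

        structure = orient_tree(
            [tuple(e) for e in payload["structure"]["edges"]], payload["structure"]["root"]
        )
        cpts = {
            node: ConditionalProbabilityTable(
                child=node,
                parent=entry["parent"],
                child_states=tuple(entry["child_states"]),
                parent_states=tuple(entry["parent_states"]),
                table=np.array(entry["table"], dtype=float),
            )
            for node, entry in payload["cpts"].items()
        }
        return cls(
            structure=structure,
            cpts=cpts,
            domains={v: tuple(s) for v, s in payload["domains"].items()},
            alpha_laplace=float(payload.get("alpha_laplace", 0.0)),
            n_fit=int(payload.get("n_fit", 0)),
        )

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "TreeBayesianNetwork":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def _domain_of(column: pd.Series) -> tuple[str, ...]:
    if isinstance(column.dtype, pd.CategoricalDtype):
        return tuple(str(c) for c in column.cat.categories)
    return tuple(sorted(str(v) for v in column.dropna().unique()))


def fit_cpts(
    structure: TreeStructure, data: pd.DataFrame, alpha_laplace: float = 0.0
) -> TreeBayesianNetwork:
    """Estimate one CPT per node by Laplace-smoothed relative frequencies.

    Entry = (count + alpha) / (row_total + alpha * n_states).  With
    alpha=0 this is the maximum-likelihood frequency estimate; a parent
    state never observed then yields a uniform row (logged warning).
    """
    if alpha_laplace < 0:
        raise ValueError("alpha_laplace must be >= 0")
    missing = [n for n in structure.nodes if n not in data.columns]
    if missing:
        raise SchemaError(f"data is missing node column(s): {missing}")
    if len(data) < 1:
        raise ValueError("at least one record is required to fit CPTs")

    domains = {n: _domain_of(data[n]) for n in structure.nodes}
    cpts: dict[str, ConditionalProbabilityTable] = {}
    for node in structure.nodes:
        parent = structure.parent[node]
        states = domains[node]
        k = len(states)
        if parent is None:
            counts = data[node].value_counts().reindex(list(states), fill_value=0).to_numpy(float)
            counts = counts[None, :]
            parent_states: tuple[str, ...] = ("",)
        else:
            ct = pd.crosstab(data[parent], data[node], dropna=False)
            ct = ct.reindex(index=list(domains[parent]), columns=list(states), fill_value=0)
            counts = ct.to_numpy(float)
            parent_states = domains[parent]
        row_totals = counts.sum(axis=1, keepdims=True)
        table = np.empty_like(counts)
        for i, total in enumerate(row_totals[:, 0]):
            if total + alpha_laplace * k == 0:
                logger.warning(
                    "fit_cpts: no observations for %r given %s=%r; using a uniform row",
                    node,
                    parent,
                    parent_states[i],
                )
                table[i] = 1.0 / k
            else:
                table[i] = (counts[i] + alpha_laplace) / (total + alpha_laplace * k)
        cpts[node] = ConditionalProbabilityTable(node, parent, states, parent_states, table)
    return TreeBayesianNetwork(
        structure=structure,
        cpts=cpts,
        domains=domains,
        alpha_laplace=alpha_laplace,
        n_fit=len(data),
    )


def prior_marginal(network: TreeBayesianNetwork, variable: str) -> PosteriorResult:
    return network.prior_marginal(variable)


def posterior(network: TreeBayesianNetwork, query: str, evidence: Evidence) -> PosteriorResult:
    return network.posterior(query, evidence)


def evidence_from_pattern(
    scheme: DiscretizationScheme,
    pattern: str,
    custom: Optional[Mapping[str, str]] = None,
) -> dict[str, str]:
    """Named evidence configuration (e.g. the full high-risk profile)
    as variable -> state assignments."""
    if pattern == "custom":
        if custom is None:
            raise ValueError("custom pattern requires explicit assignments")
        missing = [v for v in scheme.variables if v not in custom]
        if missing:
            raise ValueError(f"custom pattern missing variables: {missing}")
        return dict(custom)
    if pattern not in scheme.patterns:
        raise ValueError(f"scheme defines no pattern named {pattern!r}")
    return dict(scheme.patterns[pattern])
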