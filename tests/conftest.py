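import numpy as np
import pytest

from bullynet import (
    CohortConfig,
    DesignedSignal,
    apply_scheme,
    chow_liu_tree,
    default_bullying_scheme,
    default_help_scheme,
    fit_cpts,
    generate_cohort,
    mi_matrix,
    orient_tree,
)
from bullynet.model import ConditionalProbabilityTable, TreeBayesianNetwork
from bullynet.structure import TreeStructure


@pytest.fixture
def bullying_scheme():
    return default_bullying_scheme()


@pytest.fixture
def help_scheme():
    return default_help_scheme()


def designed_bullying_config(n=5000, seed=0, p_pos=0.95, p_neg=0.2, prevalence=0.24):
    scheme = default_bullying_scheme()
    signal = {v: DesignedSignal(p_pos, p_neg) for v in scheme.variables}
    return CohortConfig(
        n=n,
        prevalence_bullying=prevalence,
        mode="designed",
        designed_outcome="bullying",
        designed_signal=signal,
        seed=seed,
    )


def designed_help_config(n=5000, seed=0, p_pos=0.95, p_neg=0.2, prevalence=0.96):
    scheme = default_help_scheme()
    signal = {v: DesignedSignal(p_pos, p_neg) for v in scheme.variables}
    return CohortConfig(
        n=n,
        prevalence_help_seeking=prevalence,
        mode="designed",
        designed_outcome="help_seeking",
        designed_scheme=scheme,
        designed_signal=signal,
        seed=seed,
    )


def learn_network(cohort, scheme, outcome, alpha_laplace=0.0):
    """Discretize -> Chow-Liu -> orient at outcome -> fit MLE CPTs."""
    discrete = apply_scheme(cohort, scheme, outcome_columns=(outcome,))
    mi = mi_matrix(discrete)
    tree = orient_tree(chow_liu_tree(mi), root=outcome)
    return fit_cpts(tree, discrete, alpha_laplace=alpha_laplace)


def random_tree_network(rng: np.random.Generator, n_nodes: int) -> TreeBayesianNetwork:
    """Random binary tree network with Dirichlet CPT rows."""
    names = [f"v{i}" for i in range(n_nodes)]
    edges = []
    for i in range(1, n_nodes):
        parent = names[int(rng.integers(0, i))]
        edges.append(tuple(sorted((parent, names[i]))))
    structure = orient_tree(edges, root=names[0]) if n_nodes > 1 else TreeStructure(
        (names[0],), (), names[0], {names[0]: None}
    )
    states = ("a", "b")
    cpts = {}
    for node in structure.nodes:
        parent = structure.parent[node]
        rows = 1 if parent is None else 2
        table = rng.dirichlet(np.ones(2), size=rows)
        cpts[node] = ConditionalProbabilityTable(
            node, parent, states, ("",) if parent is None else states, table
        )
    return TreeBayesianNetwork(
        structure=structure,
        cpts=cpts,
        domains={n: states for n in structure.nodes},
        n_fit=100,
    )


@pytest.fixture(scope="session")
def designed_bullying_cohort():
    return generate_cohort(designed_bullying_config(seed=11))


@pytest.fixture(scope="session")
def tabled_cohort_75():
    return generate_cohort(CohortConfig(n=75, seed=3, exact_prevalence=True))
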