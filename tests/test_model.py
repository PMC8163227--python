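import itertools
import logging

import numpy as np
import pandas as pd
import pytest

from bullynet import (
    CohortConfig,
    ImpossibleEvidenceError,
    SchemaError,
    TreeBayesianNetwork,
    apply_scheme,
    default_bullying_scheme,
    default_help_scheme,
    evidence_from_pattern,
    fit_cpts,
    generate_cohort,
    orient_tree,
)
from bullynet.model import ConditionalProbabilityTable
from bullynet.structure import TreeStructure

from conftest import (
    designed_bullying_config,
    designed_help_config,
    learn_network,
    random_tree_network,
)
from oracles import enumerate_posterior


def _single_node_network(p_yes: float) -> TreeBayesianNetwork:
    structure = TreeStructure(("h",), (), "h", {"h": None})
    cpt = ConditionalProbabilityTable("h", None, ("no", "yes"), ("",), [[1 - p_yes, p_yes]])
    return TreeBayesianNetwork(structure, {"h": cpt}, {"h": ("no", "yes")})


def _two_node_data(counts: dict[tuple[str, str], int]) -> pd.DataFrame:
    rows = []
    for (p, c), k in counts.items():
        rows += [{"parent": p, "child": c}] * k
    table = pd.DataFrame(rows)
    for col in table.columns:
        table[col] = pd.Categorical(table[col], categories=["no", "yes"])
    return table


class TestFitCpts:
    def test_root_prior_is_relative_frequency(self, tabled_cohort_75):
        """18 positives among 75 records give a fitted prior of exactly 0.24."""
        scheme = default_bullying_scheme()
        discrete = apply_scheme(tabled_cohort_75, scheme, outcome_columns=("bullying",))
        edges = [("bullying", v) for v in scheme.variables]
        network = fit_cpts(orient_tree(edges, "bullying"), discrete)
        assert network.prior_marginal("bullying")["yes"] == pytest.approx(0.24, abs=0)

    def test_laplace_smoothing_hand_computation(self):
        data = _two_node_data(
            {("yes", "no"): 3, ("yes", "yes"): 1, ("no", "no"): 2, ("no", "yes"): 2}
        )
        tree = orient_tree([("child", "parent")], root="parent")
        network = fit_cpts(tree, data, alpha_laplace=1.0)
        row = network.cpts["child"].table[1]  # parent = "yes"
        assert row == pytest.approx([4 / 6, 2 / 6])

    def test_large_alpha_approaches_uniform(self):
        data = _two_node_data({("yes", "no"): 10, ("no", "yes"): 5})
        tree = orient_tree([("child", "parent")], root="parent")
        network = fit_cpts(tree, data, alpha_laplace=1e9)
        for cpt in network.cpts.values():
            assert cpt.table == pytest.approx(0.5, abs=1e-6)

    def test_unseen_parent_state_gets_uniform_row_with_warning(self, caplog):
        data = _two_node_data({("yes", "no"): 4, ("yes", "yes"): 2})
        tree = orient_tree([("child", "parent")], root="parent")
        with caplog.at_level(logging.WARNING, logger="bullynet.model"):
            network = fit_cpts(tree, data, alpha_laplace=0.0)
        assert network.cpts["child"].table[0] == pytest.approx([0.5, 0.5])
        assert "uniform" in caplog.text

    def test_missing_node_column_is_schema_error(self):
        data = _two_node_data({("yes", "no"): 4})
        tree = orient_tree([("child", "missing_var")], root="missing_var")
        with pytest.raises(SchemaError, match="missing_var"):
            fit_cpts(tree, data.rename(columns={"parent": "x"}))

    def test_cpt_rows_always_normalized(self):
        rng = np.random.default_rng(0)
        for seed in range(20):
            network = random_tree_network(np.random.default_rng(seed), 6)
            for cpt in network.cpts.values():
                assert cpt.table.sum(axis=1) == pytest.approx(1.0, abs=1e-12)
        del rng


class TestQueries:
    def test_single_node_marginal_is_cpt(self):
        network = _single_node_network(0.24)
        assert network.prior_marginal("h").probabilities == {"no": 0.76, "yes": 0.24}

    def test_empty_evidence_equals_prior(self):
        network = random_tree_network(np.random.default_rng(3), 7)
        for node in network.structure.nodes:
            prior = network.prior_marginal(node).probabilities
            post = network.posterior(node, {}).probabilities
            assert prior == post

    def test_posterior_sums_to_one(self):
        network = random_tree_network(np.random.default_rng(4), 9)
        result = network.posterior("v3", {"v0": "a", "v5": "b"})
        assert sum(result.probabilities.values()) == pytest.approx(1.0, abs=1e-12)

    def test_query_in_evidence_rejected(self):
        network = _single_node_network(0.5)
        with pytest.raises(ValueError):
            network.posterior("h", {"h": "yes"})

    def test_unknown_variable_and_state_rejected(self):
        network = random_tree_network(np.random.default_rng(5), 4)
        with pytest.raises(KeyError):
            network.posterior("nope", {})
        with pytest.raises(KeyError):
            network.posterior("v0", {"v1": "zzz"})

    def test_impossible_evidence_raises_naming_assignment(self):
        structure = orient_tree([("h", "e")], root="h")
        cpts = {
            "h": ConditionalProbabilityTable("h", None, ("no", "yes"), ("",), [[0.5, 0.5]]),
            "e": ConditionalProbabilityTable(
                "e", "h", ("no", "yes"), ("no", "yes"), [[1.0, 0.0], [1.0, 0.0]]
            ),
        }
        network = TreeBayesianNetwork(structure, cpts, {"h": ("no", "yes"), "e": ("no", "yes")})
        with pytest.raises(ImpossibleEvidenceError, match="'e': 'yes'"):
            network.posterior("h", {"e": "yes"})

    def test_message_passing_matches_enumeration_on_random_networks(self):
        """Exact inference: 100 seeded random tree networks (up to 12 binary
        nodes), random evidence; message passing equals brute-force
        enumeration of the factored joint within 1e-10."""
        checked = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n_nodes = int(rng.integers(2, 13))
            network = random_tree_network(rng, n_nodes)
            nodes = list(network.structure.nodes)
            n_evidence = int(rng.integers(0, n_nodes))
            evidence_vars = list(rng.choice(nodes, size=n_evidence, replace=False))
            evidence = {v: ("a" if rng.random() < 0.5 else "b") for v in evidence_vars}
            query = next(v for v in nodes if v not in evidence)
            expected = enumerate_posterior(network, query, evidence)
            actual = network.posterior(query, evidence).probabilities
            for state in ("a", "b"):
                assert actual[state] == pytest.approx(expected[state], abs=1e-10)
            checked += 1
        assert checked == 100

    def test_full_evidence_posterior_is_empirical_conditional(self):
        """MLE CPTs reproduce training-data conditional frequencies exactly
        when the evidence is the query's entire Markov blanket and that
        blanket is a single factor (two-node network): P(h | e) is then
        p(h)p(e|h)/p(e) with every term an observed relative frequency."""
        rng = np.random.default_rng(21)
        h = rng.random(400) < 0.3
        e = np.where(rng.random(400) < 0.8, h, ~h)
        data = pd.DataFrame(
            {
                "h": pd.Categorical(np.where(h, "yes", "no"), categories=["no", "yes"]),
                "e": pd.Categorical(np.where(e, "yes", "no"), categories=["no", "yes"]),
            }
        )
        network = fit_cpts(orient_tree([("e", "h")], root="h"), data)
        for state in ("yes", "no"):
            empirical = (data.loc[data["e"] == state, "h"] == "yes").mean()
            assert network.posterior("h", {"e": state})["yes"] == pytest.approx(
                empirical, abs=1e-12
            )

    def test_orientation_invariance(self, designed_bullying_cohort):
        """Re-rooting the tree and refitting MLE CPTs leaves every posterior
        unchanged: orientation is presentation, not modeling."""
        scheme = default_bullying_scheme()
        discrete = apply_scheme(
            designed_bullying_cohort, scheme, outcome_columns=("bullying",)
        )
        from bullynet import chow_liu_tree, mi_matrix

        edges = chow_liu_tree(mi_matrix(discrete))
        evidence = dict(
            list(evidence_from_pattern(scheme, "high_risk").items())[:3]
        )
        reference = None
        for root in ("bullying", "eas_distress", "sor_balanced_cohesion"):
            network = fit_cpts(orient_tree(edges, root), discrete)
            post = network.posterior("bullying", evidence)["yes"]
            if reference is None:
                reference = post
            else:
                assert post == pytest.approx(reference, abs=1e-10)

    def test_conditioning_monotonicity(self, designed_bullying_cohort):
        """Adding one more risk-state evidence variable never decreases the
        posterior when that variable's likelihood ratio exceeds 1."""
        scheme = default_bullying_scheme()
        network = learn_network(designed_bullying_cohort, scheme, "bullying")
        pattern = evidence_from_pattern(scheme, "high_risk")
        evidence: dict[str, str] = {}
        last = network.prior_marginal("bullying")["yes"]
        for var, state in pattern.items():
            evidence[var] = state
            current = network.posterior("bullying", evidence)["yes"]
            assert current >= last - 1e-12
            last = current


class TestPatternsAndSerialization:
    def test_bullying_patterns(self):
        scheme = default_bullying_scheme()
        high = evidence_from_pattern(scheme, "high_risk")
        low = evidence_from_pattern(scheme, "low_risk")
        assert high["eas_distress"] == "high" and high["sor_balanced_cohesion"] == "low"
        assert low == {v: ("low" if s == "high" else "high") for v, s in high.items()}

    def test_help_low_risk_pattern(self):
        low = evidence_from_pattern(default_help_scheme(), "low_risk")
        assert low == {
            "sor_family_satisfaction": "low",
            "sor_family_communication": "low",
            "eas_sociability": "low",
        }

    def test_custom_pattern_requires_all_variables(self):
        scheme = default_help_scheme()
        with pytest.raises(ValueError, match="missing"):
            evidence_from_pattern(scheme, "custom", custom={"eas_sociability": "high"})

    def test_unknown_pattern_name(self):
        with pytest.raises(ValueError):
            evidence_from_pattern(default_help_scheme(), "medium_risk")

    def test_json_round_trip_preserves_posteriors(self, tmp_path, designed_bullying_cohort):
        network = learn_network(
            designed_bullying_cohort, default_bullying_scheme(), "bullying"
        )
        path = tmp_path / "net.json"
        network.to_json(path)
        restored = TreeBayesianNetwork.from_json(path)
        assert restored.structure.edges == network.structure.edges
        evidence = evidence_from_pattern(default_bullying_scheme(), "high_risk")
        assert restored.posterior("bullying", evidence)["yes"] == network.posterior(
            "bullying", evidence
        )["yes"]
        for node, cpt in network.cpts.items():
            assert np.array_equal(restored.cpts[node].table, cpt.table)

    def test_posteriors_reported_after_designed_simulation(self):
        """Sanity anchor: prior 0.24 with six 0.95/0.2 predictors pushes the
        all-risk posterior above 0.99 (analytic odds 0.316 * 4.75^6)."""
        cohort = generate_cohort(designed_bullying_config(n=5000, seed=2))
        scheme = default_bullying_scheme()
        network = learn_network(cohort, scheme, "bullying")
        high = network.posterior(
            "bullying", evidence_from_pattern(scheme, "high_risk")
        )["yes"]
        assert high >= 0.99

    def test_help_model_posterior_extremes(self):
        cohort = generate_cohort(designed_help_config(n=5000, seed=2))
        scheme = default_help_scheme()
        network = learn_network(cohort, scheme, "help_seeking")
        high = network.posterior(
            "help_seeking", evidence_from_pattern(scheme, "high_risk")
        )["yes"]
        low = network.posterior(
            "help_seeking", evidence_from_pattern(scheme, "low_risk")
        )["yes"]
        assert high >= 0.99
        assert low <= 0.01
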