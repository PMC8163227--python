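"""End-to-end analysis pipeline.

Composes the stages: cohort generation/loading -> group comparisons ->
discretization -> Chow-Liu structure learning -> CPT estimation ->
prior and posterior queries, for both outcome models (bullying and
help-seeking), each with its own variable subset and discretization
scheme.  Fully deterministic given the seed in the cohort config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import cohort as cohort_mod
from . import group_stats, structure
from .discretize import (
    DiscretizationScheme,
    apply_scheme,
    default_bullying_scheme,
    default_help_scheme,
)
from .model import (
    ImpossibleEvidenceError,
    TreeBayesianNetwork,
    evidence_from_pattern,
    fit_cpts,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the original error."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Configuration of one full run.

    ``cohort`` is either a :class:`~bullynet.cohort.CohortConfig` for a
    synthetic cohort or a path to a cohort CSV.  The default synthetic
    cohort pins the outcome counts to the study's observed 18/75 and
    72/75 so the fitted priors are 0.24 and 0.96.
    """

    cohort: "cohort_mod.CohortConfig | str" = field(
        default_factory=lambda: cohort_mod.CohortConfig(exact_prevalence=True)
    )
    alpha_laplace: float = 0.0
    predictor_alpha: float = 0.01
    bullying_scheme: DiscretizationScheme = field(default_factory=default_bullying_scheme)
    help_scheme: DiscretizationScheme = field(default_factory=default_help_scheme)
    out_dir: Optional[str] = None


@dataclass
class OutcomeModelResult:
    outcome: str
    scheme: DiscretizationScheme
    mi: pd.DataFrame
    structure: structure.TreeStructure
    network: TreeBayesianNetwork
    predictors: set[str]
    prior: dict[str, float]
    #: None when the pattern has zero fitted probability (possible for
    #: small cohorts with unsmoothed CPTs)
    posterior_high: Optional[dict[str, float]]
    posterior_low: Optional[dict[str, float]]


@dataclass
class AnalysisReport:
    cohort_summary: dict
    comparisons: dict[str, list[group_stats.GroupComparisonResult]]
    models: dict[str, OutcomeModelResult]
    config_echo: dict

    def to_dict(self) -> dict:
        return {
            "cohort_summary": self.cohort_summary,
            "comparisons": {
                outcome: [dataclasses.asdict(r) for r in rows]
                for outcome, rows in self.comparisons.items()
            },
            "models": {
                outcome: {
                    "scheme": m.scheme.to_dict(),
                    "edges": [list(e) for e in m.structure.edges],
                    "root": m.structure.root,
                    "predictors": sorted(m.predictors),
                    "prior": m.prior,
                    "posterior_high_risk": m.posterior_high,
                    "posterior_low_risk": m.posterior_low,
                }
                for outcome, m in self.models.items()
            },
            "config": self.config_echo,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def to_markdown(self) -> str:
        d = self.to_dict()
        lines = ["# Cohort analysis report", "", "## Cohort"]
        for k, v in d["cohort_summary"].items():
            lines.append(f"- {k}: {v}")
        for outcome, rows in self.comparisons.items():
            pos, neg = f"{outcome}=yes", f"{outcome}=no"
            lines += ["", f"## Group comparison by {outcome}", ""]
            lines.append(group_stats.results_to_markdown(rows, pos, neg))
        for outcome, m in d["models"].items():
            lines += ["", f"## Model: {outcome}", ""]
            lines.append(f"- tree edges: {m['edges']}")
            lines.append(f"- predictors (G-test): {m['predictors']}")
            lines.append(f"- prior P({outcome}=yes) = {m['prior']['yes']:.4f}")
            for label, key in (
                ("high-risk", "posterior_high_risk"),
                ("low-risk", "posterior_low_risk"),
            ):
                post = m[key]
                rendered = (
                    f"{post['yes']:.4f}"
                    if post is not None
                    else "undefined (pattern has zero fitted probability)"
                )
                lines.append(f"- posterior P({outcome}=yes | {label} pattern) = {rendered}")
        lines += ["", "## Config", "", "```json", json.dumps(d["config"], indent=2), "```", ""]
        return "\n".join(lines)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc

        return wrapped

    return deco


@_stage("cohort")
def _load_cohort(config: PipelineConfig) -> pd.DataFrame:
    if isinstance(config.cohort, (str, Path)):
        return cohort_mod.read_cohort(config.cohort)
    return cohort_mod.generate_cohort(config.cohort)


@_stage("compare_groups")
def _comparisons(cohort: pd.DataFrame, outcome: str):
    return group_stats.compare_groups(cohort, outcome)


@_stage("model")
def _fit_outcome_model(
    cohort: pd.DataFrame,
    outcome: str,
    scheme: DiscretizationScheme,
    alpha_laplace: float,
    predictor_alpha: float,
) -> OutcomeModelResult:
    discrete = apply_scheme(cohort, scheme, outcome_columns=(outcome,))
    variables = [*scheme.variables, outcome]
    mi = structure.mi_matrix(discrete, variables)
    edges = structure.chow_liu_tree(mi)
    tree = structure.orient_tree(edges, root=outcome)
    network = fit_cpts(tree, discrete, alpha_laplace=alpha_laplace)
    predictors = structure.identify_predictors(network, outcome, alpha=predictor_alpha)
    prior = network.prior_marginal(outcome).probabilities

    def _pattern_posterior(name: str) -> Optional[dict[str, float]]:
        evidence = evidence_from_pattern(scheme, name)
        try:
            return network.posterior(outcome, evidence).probabilities
        except ImpossibleEvidenceError:
            logger.warning(
                "pipeline: %s pattern for %r has zero fitted probability "
                "(zero-frequency cells); posterior undefined",
                name,
                outcome,
            )
            return None

    high = _pattern_posterior("high_risk")
    low = _pattern_posterior("low_risk")
    return OutcomeModelResult(
        outcome=outcome,
        scheme=scheme,
        mi=mi,
        structure=tree,
        network=network,
        predictors=predictors,
        prior=prior,
        posterior_high=high,
        posterior_low=low,
    )


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Run the full two-model analysis and (optionally) write artifacts."""
    cohort = _load_cohort(config)
    summary = {
        "n": int(len(cohort)),
        "n_bullying": int(cohort["bullying"].sum()),
        "n_help_seeking": int(cohort["help_seeking"].sum()),
    }
    logger.info("pipeline: cohort of %d records", summary["n"])

    comparisons = {}
    models = {}
    for outcome, scheme in (
        ("bullying", config.bullying_scheme),
        ("help_seeking", config.help_scheme),
    ):
        comparisons[outcome] = _comparisons(cohort, outcome)
        models[outcome] = _fit_outcome_model(
            cohort, outcome, scheme, config.alpha_laplace, config.predictor_alpha
        )

    if isinstance(config.cohort, (str, Path)):
        cohort_echo: dict = {"source": str(config.cohort)}
    else:
        cohort_echo = {
            k: v
            for k, v in dataclasses.asdict(config.cohort).items()
            if not isinstance(v, (DiscretizationScheme,)) and k != "designed_scheme"
        }
        cohort_echo["designed_signal"] = (
            {v: dataclasses.asdict(s) for v, s in config.cohort.designed_signal.items()}
            if config.cohort.designed_signal
            else None
        )
    report = AnalysisReport(
        cohort_summary=summary,
        comparisons=comparisons,
        models=models,
        config_echo={
            "cohort": cohort_echo,
            "alpha_laplace": config.alpha_laplace,
            "predictor_alpha": config.predictor_alpha,
        },
    )

    if config.out_dir is not None:
        _write_artifacts(config, cohort, report)
    return report


@_stage("write_artifacts")
def _write_artifacts(config: PipelineConfig, cohort: pd.DataFrame, report: AnalysisReport) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_mod.write_cohort(cohort, out / "cohort.csv")
    (out / "report.md").write_text(report.to_markdown(), encoding="utf-8")
    (out / "report.json").write_text(report.to_json(), encoding="utf-8")
    for outcome, m in report.models.items():
        m.network.to_json(out / f"network_{outcome}.json")
        structure.write_dot(m.structure, out / f"network_{outcome}.dot")
        m.mi.to_csv(out / f"mi_{outcome}.csv")
        group_stats.results_to_frame(report.comparisons[outcome]).to_csv(
            out / f"comparison_{outcome}.csv", index=False
        )
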