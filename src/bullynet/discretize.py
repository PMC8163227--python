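"""Threshold discretization of questionnaire subscale scores.

Each modeled subscale is mapped to a two-state categorical ("low"/"high")
by a single cut-point.  The boundary convention is stored per rule because
the screening patterns mix strict and non-strict thresholds across
variables (e.g. Distress "more than 12.5" vs Family Communication "higher
or equal to 22.5"); half-integer cut-points make the two conventions
coincide on integer scores, but integer cut-points (Fear at 9, Family
Satisfaction at 12) do not.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STRICTLY_GREATER = "strictly_greater"
GREATER_OR_EQUAL = "greater_or_equal"

#: categorical state labels, low state first
DEFAULT_STATES = ("low", "high")
#: outcome flags are carried through discretization as two-state categoricals
OUTCOME_STATES = ("no", "yes")
OUTCOME_COLUMNS = ("bullying", "help_seeking")


class SchemaError(ValueError):
    """A required variable or column is missing or inconsistent."""


class NoValidCutError(ValueError):
    """No admissible cut-point exists (e.g. constant scores)."""


@dataclass(frozen=True)
class CutRule:
    """One variable's binarization rule.

    ``elevated_when`` chooses whether scores equal to ``cut_point`` fall in
    the high state (``greater_or_equal``) or the low state
    (``strictly_greater``).
    """

    variable: str
    cut_point: float
    elevated_when: str = STRICTLY_GREATER
    state_labels: tuple[str, str] = DEFAULT_STATES

    def __post_init__(self) -> None:
        if self.elevated_when not in (STRICTLY_GREATER, GREATER_OR_EQUAL):
            raise ValueError(f"unknown boundary convention {self.elevated_when!r}")
        if len(self.state_labels) != 2 or len(set(self.state_labels)) != 2:
            raise ValueError("state_labels must be two distinct labels")

    def is_high(self, values) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.elevated_when == STRICTLY_GREATER:
            return values > self.cut_point
        return values >= self.cut_point

    def states(self, values) -> pd.Categorical:
        low, high = self.state_labels
        labels = np.where(self.is_high(values), high, low)
        return pd.Categorical(labels, categories=list(self.state_labels))

    def side_integers(self, lo: int, hi: int) -> tuple[np.ndarray, np.ndarray]:
        """Integer scores in [lo, hi] falling on the (low, high) side."""
        grid = np.arange(lo, hi + 1)
        high = self.is_high(grid)
        return grid[~high], grid[high]


@dataclass
class DiscretizationScheme:
    """Ordered set of cut rules, one per modeled variable.

    ``patterns`` holds named evidence configurations (state assignment per
    modeled variable), e.g. the published high-risk score profile.
    """

    rules: tuple[CutRule, ...]
    patterns: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rules = tuple(self.rules)
        names = [r.variable for r in self.rules]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variables in scheme")
        for pattern in self.patterns.values():
            for var in pattern:
                if var not in names:
                    raise ValueError(f"pattern references unknown variable {var!r}")

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(r.variable for r in self.rules)

    def rule_for(self, variable: str) -> CutRule:
        for rule in self.rules:
            if rule.variable == variable:
                return rule
        raise KeyError(variable)

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "rules": [
                {
                    "variable": r.variable,
                    "cut_point": r.cut_point,
                    "elevated_when": r.elevated_when,
                    "state_labels": list(r.state_labels),
                }
                for r in self.rules
            ],
            "patterns": self.patterns,
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "DiscretizationScheme":
        rules = tuple(
            CutRule(
                variable=r["variable"],
                cut_point=float(r["cut_point"]),
                elevated_when=r["elevated_when"],
                state_labels=tuple(r["state_labels"]),
            )
            for r in payload["rules"]
        )
        patterns = {k: dict(v) for k, v in payload.get("patterns", {}).items()}
        return cls(rules=rules, patterns=patterns)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "DiscretizationScheme":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def default_bullying_scheme() -> DiscretizationScheme:
    """The six-variable bullying screen: cut-points and boundary wording.

    High-risk profile: elevated Distress, Fear, Activity and Sociability
    combined with low Balanced Cohesion and low Balanced Flexibility.
    """
    rules = (
        CutRule("eas_distress", 12.5, STRICTLY_GREATER),
        CutRule("eas_fear", 9, STRICTLY_GREATER),
        CutRule("eas_activity", 12.5, STRICTLY_GREATER),
        CutRule("eas_sociability", 9, STRICTLY_GREATER),
        CutRule("sor_balanced_cohesion", 34.5, STRICTLY_GREATER),
        CutRule("sor_balanced_flexibility", 27.5, STRICTLY_GREATER),
    )
    high_risk = {
        "eas_distress": "high",
        "eas_fear": "high",
        "eas_activity": "high",
        "eas_sociability": "high",
        "sor_balanced_cohesion": "low",
        "sor_balanced_flexibility": "low",
    }
    low_risk = {v: _other_state(s) for v, s in high_risk.items()}
    return DiscretizationScheme(rules, {"high_risk": high_risk, "low_risk": low_risk})


def default_help_scheme() -> DiscretizationScheme:
    """The three-variable help-seeking screen.

    The favorable ("high_risk" of seeking help, i.e. all-favorable)
    profile is elevated Family Satisfaction, Family Communication and
    Sociability; note Communication uses a non-strict boundary.
    """
    rules = (
        CutRule("sor_family_satisfaction", 12, STRICTLY_GREATER),
        CutRule("sor_family_communication", 22.5, GREATER_OR_EQUAL),
        CutRule("eas_sociability", 12.5, STRICTLY_GREATER),
    )
    high = {
        "sor_family_satisfaction": "high",
        "sor_family_communication": "high",
        "eas_sociability": "high",
    }
    low = {v: _other_state(s) for v, s in high.items()}
    return DiscretizationScheme(rules, {"high_risk": high, "low_risk": low})


def _other_state(state: str, labels: Sequence[str] = DEFAULT_STATES) -> str:
    low, high = labels
    return low if state == high else high


def apply_scheme(
    cohort: pd.DataFrame,
    scheme: DiscretizationScheme,
    outcome_columns: Iterable[str] = OUTCOME_COLUMNS,
) -> pd.DataFrame:
    """Discretize the modeled subscales of a cohort.

    Records with missing values in any modeled variable are dropped
    (listwise deletion) with the count logged.  Outcome flags present in
    the cohort pass through as "no"/"yes" categoricals.
    """
    missing_cols = [v for v in scheme.variables if v not in cohort.columns]
    if missing_cols:
        raise SchemaError(f"scheme variables absent from cohort: {missing_cols}")

    modeled = list(scheme.variables)
    keep = cohort[modeled].notna().all(axis=1) if len(cohort) else pd.Series(dtype=bool)
    dropped = int(len(cohort) - keep.sum()) if len(cohort) else 0
    if dropped:
        logger.info("apply_scheme: dropped %d record(s) with missing modeled values", dropped)
    data = cohort.loc[keep] if len(cohort) else cohort

    out = pd.DataFrame(index=data.index)
    for rule in scheme.rules:
        out[rule.variable] = rule.states(data[rule.variable]) if len(data) else pd.Categorical(
            [], categories=list(rule.state_labels)
        )
    for col in outcome_columns:
        if col in cohort.columns:
            if len(data):
                labels = np.where(data[col].astype(bool), "yes", "no")
            else:
                labels = []
            out[col] = pd.Categorical(labels, categories=list(OUTCOME_STATES))
    return out


def learn_cut_point(scores, outcome) -> float:
    """Supervised cut-point: the midpoint between adjacent observed scores
    maximizing mutual information between the binarized score and the
    outcome; ties broken toward the smaller cut.

    Offered as a plausible reconstruction of how half-integer screening
    thresholds arise from data; exact provenance of published cut-points
    is not asserted.
    """
    from .structure import mutual_information  # local import avoids cycle

    scores = np.asarray(scores, dtype=float)
    outcome = np.asarray(outcome, dtype=bool)
    if scores.shape != outcome.shape:
        raise ValueError("scores and outcome must have equal length")
    if outcome.all() or not outcome.any():
        raise NoValidCutError("both outcome classes must be present")
    distinct = np.unique(scores)
    if distinct.size < 2:
        raise NoValidCutError("scores are constant; no cut-point separates them")

    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    best_cut, best_mi = None, -np.inf
    for cut in candidates:
        high = scores > cut
        counts = np.array(
            [
                [np.sum(~high & ~outcome), np.sum(~high & outcome)],
                [np.sum(high & ~outcome), np.sum(high & outcome)],
            ]
        )
        mi = mutual_information(counts)
        if mi > best_mi + 1e-15:  # strict improvement; ties keep smaller cut
            best_cut, best_mi = float(cut), mi
    return best_cut
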