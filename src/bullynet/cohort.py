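"""Synthetic questionnaire cohorts.

The study data (75 Polish school students, EAS temperament and FACES
IV-SOR family-functioning subscales, self-reported bullying and
help-seeking flags) were never deposited, so every downstream stage is
exercised on cohorts generated here.  Two generative modes:

``tabled``
    Scores are drawn from group-conditional normal distributions whose
    means/SDs default to the published group descriptives, rounded to
    integers and clipped to the instrument range.  Emotionality is the
    sum of its Distress, Fear and Anger components, as the instrument
    defines it.  Subscales are conditionally independent given the
    outcome class; the published tables report no within-group
    correlations, so none are imposed.

``designed``
    Each predictor's *discretized* state is drawn given the outcome
    class with a configured probability of the outcome-favoring
    ("pattern") state, then an integer score is placed uniformly on the
    matching side of that variable's cut-point.  This gives analytically
    known likelihood ratios for structure-recovery and posterior-bound
    experiments.  Emotionality is deliberately generated as an
    independent class-null variable here (the composite identity is
    broken) so recovery tests have genuine null EAS variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .discretize import (
    DiscretizationScheme,
    SchemaError,
    default_bullying_scheme,
    default_help_scheme,
)

#: integer instrument range per subscale (items x 1-5 Likert)
SCORE_RANGES: dict[str, tuple[int, int]] = {
    "eas_distress": (4, 20),
    "eas_fear": (4, 20),
    "eas_anger": (4, 20),
    "eas_activity": (4, 20),
    "eas_sociability": (4, 20),
    "eas_emotionality": (12, 60),
    "sor_balanced_cohesion": (7, 35),
    "sor_balanced_flexibility": (7, 35),
    "sor_family_communication": (10, 50),
    "sor_family_satisfaction": (10, 50),
}

EMOTIONALITY_COMPONENTS = ("eas_distress", "eas_fear", "eas_anger")

#: subscales sampled directly in tabled mode (Emotionality is derived)
PRIMARY_SUBSCALES = tuple(v for v in SCORE_RANGES if v != "eas_emotionality")

SUBSCALES = tuple(SCORE_RANGES)

REQUIRED_COLUMNS = ("id", "sex", "age_years", *SUBSCALES, "bullying", "help_seeking")

#: group-conditional (mean, sd) keyed by subscale -> outcome class,
#: conditioning on the bullying flag (bullies n=18 vs non-bullies n=57)
BULLYING_GROUP_PARAMS: dict[str, dict[bool, tuple[float, float]]] = {
    "eas_distress": {True: (11.28, 3.10), False: (9.17, 2.43)},
    "eas_fear": {True: (9.89, 3.41), False: (9.67, 2.79)},
    "eas_anger": {True: (11.55, 3.55), False: (11.37, 2.78)},
    "eas_activity": {True: (12.33, 3.10), False: (12.33, 2.38)},
    "eas_sociability": {True: (15.17, 3.36), False: (16.56, 2.24)},
    "sor_balanced_cohesion": {True: (28.78, 5.27), False: (28.26, 5.15)},
    "sor_balanced_flexibility": {True: (23.56, 4.15), False: (24.42, 4.84)},
    "sor_family_communication": {True: (37.17, 8.79), False: (36.79, 9.13)},
    "sor_family_satisfaction": {True: (38.83, 9.03), False: (37.98, 7.41)},
}

#: same, conditioning on the help-seeking flag (seekers n=72 vs non-seekers n=3)
HELP_GROUP_PARAMS: dict[str, dict[bool, tuple[float, float]]] = {
    "eas_distress": {True: (9.62, 2.67), False: (11.00, 4.59)},
    "eas_fear": {True: (9.69, 2.94), False: (10.33, 3.21)},
    "eas_anger": {True: (11.37, 2.84), False: (12.33, 6.03)},
    "eas_activity": {True: (12.29, 2.59), False: (13.33, 1.53)},
    "eas_sociability": {True: (16.29, 2.51), False: (14.67, 4.62)},
    "sor_balanced_cohesion": {True: (28.71, 4.93), False: (20.67, 4.94)},
    "sor_balanced_flexibility": {True: (24.35, 4.72), False: (21.00, 2.00)},
    "sor_family_communication": {True: (37.35, 8.58), False: (25.67, 13.65)},
    "sor_family_satisfaction": {True: (38.37, 7.86), False: (33.67, 2.89)},
}

# demographic composition of the study group: 43/75 girls, 17/75 aged 13
_P_GIRL = 43 / 75
_P_AGE13 = 17 / 75


class ConfigError(ValueError):
    """Invalid cohort configuration."""


@dataclass(frozen=True)
class DesignedSignal:
    """Class-conditional probability of a predictor's pattern state.

    ``p_pattern_positive`` is P(state = outcome-favoring pattern state |
    outcome class positive); ``p_pattern_negative`` the same given the
    negative class.
    """

    p_pattern_positive: float
    p_pattern_negative: float

    def __post_init__(self) -> None:
        for p in (self.p_pattern_positive, self.p_pattern_negative):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"signal probability {p} outside [0, 1]")


@dataclass
class CohortConfig:
    """Configuration of one synthetic cohort.

    Defaults reproduce the study conditions: n=75, bullying prevalence
    18/75 = 0.24, help-seeking prevalence 72/75 = 0.96, tabled mode with
    the published bullying-group descriptives.
    """

    n: int = 75
    prevalence_bullying: float = 0.24
    prevalence_help_seeking: float = 0.96
    mode: str = "tabled"
    tabled_outcome: str = "bullying"
    tabled_params: Optional[Mapping[str, Mapping[bool, tuple[float, float]]]] = None
    designed_outcome: str = "bullying"
    designed_scheme: Optional[DiscretizationScheme] = None
    designed_signal: Optional[Mapping[str, DesignedSignal]] = None
    designed_pattern: str = "high_risk"
    exact_prevalence: bool = False
    seed: int = 0
    score_ranges: Mapping[str, tuple[int, int]] = field(default_factory=lambda: dict(SCORE_RANGES))

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigError(f"cohort size must be >= 1, got {self.n}")
        for name, p in (
            ("prevalence_bullying", self.prevalence_bullying),
            ("prevalence_help_seeking", self.prevalence_help_seeking),
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}={p} outside [0, 1]")
        if self.mode not in ("tabled", "designed"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.tabled_outcome not in ("bullying", "help_seeking"):
            raise ConfigError(f"unknown tabled_outcome {self.tabled_outcome!r}")
        if self.designed_outcome not in ("bullying", "help_seeking"):
            raise ConfigError(f"unknown designed_outcome {self.designed_outcome!r}")
        params = self.tabled_params or self._default_tabled_params()
        for var, groups in params.items():
            if var not in self.score_ranges:
                raise ConfigError(f"unknown subscale {var!r} in tabled_params")
            for _, (_, sd) in groups.items():
                if sd <= 0:
                    raise ConfigError(f"SD for {var!r} must be > 0, got {sd}")

    def _default_tabled_params(self):
        return BULLYING_GROUP_PARAMS if self.tabled_outcome == "bullying" else HELP_GROUP_PARAMS

    def _default_designed_scheme(self) -> DiscretizationScheme:
        return default_bullying_scheme() if self.designed_outcome == "bullying" else default_help_scheme()


def _draw_flags(rng: np.random.Generator, n: int, p: float, exact: bool) -> np.ndarray:
    if exact:
        k = int(round(p * n))
        flags = np.zeros(n, dtype=bool)
        flags[rng.permutation(n)[:k]] = True
        return flags
    return rng.random(n) < p


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate one cohort DataFrame (one row per student).

    Deterministic given the config (including the seed).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n

    bullying = _draw_flags(rng, n, config.prevalence_bullying, config.exact_prevalence)
    help_seeking = _draw_flags(rng, n, config.prevalence_help_seeking, config.exact_prevalence)

    records = pd.DataFrame(
        {
            "id": [f"S{i + 1:05d}" for i in range(n)],
            "sex": np.where(rng.random(n) < _P_GIRL, "girl", "boy"),
            "age_years": np.where(rng.random(n) < _P_AGE13, 13, 14).astype(int),
        }
    )

    if config.mode == "tabled":
        scores = _tabled_scores(rng, config, bullying, help_seeking)
    else:
        scores = _designed_scores(rng, config, bullying, help_seeking)

    for var in SUBSCALES:
        records[var] = scores[var]
    records["bullying"] = bullying
    records["help_seeking"] = help_seeking
    return records


def _discrete_moments(mu: float, sigma: float, lo: int, hi: int) -> tuple[float, float]:
    """Mean and SD of round-then-clip applied to N(mu, sigma) on [lo, hi]."""
    from scipy.stats import norm

    grid = np.arange(lo, hi + 1)
    upper = norm.cdf((grid + 0.5 - mu) / sigma)
    lower = norm.cdf((grid - 0.5 - mu) / sigma)
    p = upper - lower
    p[0] += lower[0]  # mass below lo-0.5 clips to lo
    p[-1] += 1.0 - upper[-1]  # mass above hi+0.5 clips to hi
    mean = float(np.sum(grid * p))
    var = float(np.sum((grid - mean) ** 2 * p))
    return mean, np.sqrt(var)


@lru_cache(maxsize=None)
def _calibrated_normal(target_mean: float, target_sd: float, lo: int, hi: int) -> tuple[float, float]:
    """Latent (mu, sigma) whose rounded-and-clipped integer distribution has
    the target mean and SD.

    Rounding inflates and boundary clipping deflates/biases the moments;
    without this inversion the wide 10-50 scales would miss their printed
    group means by several tenths.  Falls back to the uncorrected
    parameters if no solution exists inside the range.
    """
    from scipy import optimize

    def residual(x):
        mu, log_sigma = x
        m, s = _discrete_moments(mu, np.exp(log_sigma), lo, hi)
        return [m - target_mean, s - target_sd]

    sol = optimize.root(residual, x0=[target_mean, np.log(target_sd)], method="hybr")
    if sol.success and np.max(np.abs(sol.fun)) < 1e-6:
        return float(sol.x[0]), float(np.exp(sol.x[1]))
    logger_warning = (
        "calibration failed for mean=%s sd=%s on [%s, %s]; using uncorrected parameters"
    )
    import logging

    logging.getLogger(__name__).warning(logger_warning, target_mean, target_sd, lo, hi)
    return target_mean, target_sd


def _tabled_scores(rng, config: CohortConfig, bullying, help_seeking) -> dict[str, np.ndarray]:
    params = config.tabled_params or config._default_tabled_params()
    group = bullying if config.tabled_outcome == "bullying" else help_seeking
    scores: dict[str, np.ndarray] = {}
    for var in PRIMARY_SUBSCALES:
        lo, hi = config.score_ranges[var]
        mu_pos, sd_pos = _calibrated_normal(*params[var][True], lo, hi)
        mu_neg, sd_neg = _calibrated_normal(*params[var][False], lo, hi)
        mean = np.where(group, mu_pos, mu_neg)
        sd = np.where(group, sd_pos, sd_neg)
        raw = rng.normal(mean, sd)
        scores[var] = np.clip(np.rint(raw), lo, hi).astype(int)
    scores["eas_emotionality"] = sum(scores[c] for c in EMOTIONALITY_COMPONENTS)
    return scores


def _designed_scores(rng, config: CohortConfig, bullying, help_seeking) -> dict[str, np.ndarray]:
    scheme = config.designed_scheme or config._default_designed_scheme()
    signal = dict(config.designed_signal or {})
    for var in signal:
        if var not in scheme.variables:
            raise ConfigError(f"designed signal variable {var!r} has no cut rule in the scheme")
    if config.designed_pattern not in scheme.patterns:
        raise ConfigError(f"scheme has no pattern named {config.designed_pattern!r}")
    pattern = scheme.patterns[config.designed_pattern]
    cls = bullying if config.designed_outcome == "bullying" else help_seeking

    scores: dict[str, np.ndarray] = {}
    for var in SUBSCALES:
        lo, hi = config.score_ranges[var]
        if var in signal:
            rule = scheme.rule_for(var)
            low_side, high_side = rule.side_integers(lo, hi)
            pattern_state = pattern[var]
            pattern_side = high_side if pattern_state == rule.state_labels[1] else low_side
            other_side = low_side if pattern_side is high_side else high_side
            if len(pattern_side) == 0 or len(other_side) == 0:
                raise ConfigError(f"cut-point for {var!r} leaves one side empty")
            sig = signal[var]
            p = np.where(cls, sig.p_pattern_positive, sig.p_pattern_negative)
            in_pattern = rng.random(len(cls)) < p
            vals = np.where(
                in_pattern,
                rng.choice(pattern_side, size=len(cls)),
                rng.choice(other_side, size=len(cls)),
            )
            scores[var] = vals.astype(int)
        else:
            # class-null variable: uniform over the full instrument range
            scores[var] = rng.integers(lo, hi + 1, size=len(cls))
    return scores


def write_cohort(cohort: pd.DataFrame, destination) -> None:
    """Write a cohort as UTF-8 CSV with header; missing values as empty fields."""
    cohort.to_csv(destination, index=False)


def read_cohort(source) -> pd.DataFrame:
    """Read a cohort CSV; unknown extra columns are preserved.

    Raises :class:`SchemaError` naming any required column that is absent.
    """
    table = pd.read_csv(source)
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"cohort file missing required column(s): {missing}")
    for col in ("bullying", "help_seeking"):
        table[col] = table[col].astype(bool)
    for var in SUBSCALES:
        if table[var].notna().all():
            table[var] = table[var].astype(int)
    table["age_years"] = table["age_years"].astype(int)
    return table
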