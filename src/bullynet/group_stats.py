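"""Group descriptives and Mann-Whitney U comparisons.

Reproduces the descriptive stage of the analysis: for each subscale,
means and SDs per outcome group plus a two-sided Mann-Whitney U test.
U is reported as min(U_A, U_B), the smaller of the two one-sided pair
counts.  The p-value is exact (null enumeration) when n1*n2 <= 400 and
the pooled sample has no ties; otherwise the normal approximation with
tie correction and continuity correction is used.  No multiple-testing
correction is applied, matching the descriptive-table convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import SUBSCALES

EXACT_MAX_PAIRS = 400


@dataclass
class GroupComparisonResult:
    variable: str
    n_a: int
    n_b: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    u: float
    p: float
    method: str = "asymptotic"


def mann_whitney_u(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: returns (min(U_A, U_B), p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    u, p, _ = _mann_whitney(a, b)
    return u, p


def _mann_whitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float, str]:
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if n1 * n2 <= EXACT_MAX_PAIRS and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u_a = float(res.statistic)
    u = min(u_a, n1 * n2 - u_a)
    return u, float(min(res.pvalue, 1.0)), method


def compare_groups(
    cohort: pd.DataFrame, outcome: str, variables=SUBSCALES
) -> list[GroupComparisonResult]:
    """One descriptive comparison per subscale between outcome groups.

    Group A is the outcome-positive class (e.g. bullies), group B the
    rest, matching the published table layout.
    """
    if outcome not in cohort.columns:
        raise KeyError(f"outcome column {outcome!r} not in cohort")
    flags = cohort[outcome].astype(bool)
    if flags.all() or not flags.any():
        raise ValueError(f"outcome {outcome!r} has a single class; nothing to compare")
    results = []
    for var in variables:
        a = cohort.loc[flags, var].dropna().to_numpy(float)
        b = cohort.loc[~flags, var].dropna().to_numpy(float)
        u, p, method = _mann_whitney(a, b)
        results.append(
            GroupComparisonResult(
                variable=var,
                n_a=a.size,
                n_b=b.size,
                mean_a=float(a.mean()),
                sd_a=float(a.std(ddof=1)) if a.size > 1 else float("nan"),
                mean_b=float(b.mean()),
                sd_b=float(b.std(ddof=1)) if b.size > 1 else float("nan"),
                u=u,
                p=p,
                method=method,
            )
        )
    return results


def results_to_frame(results: list[GroupComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variable": [r.variable for r in results],
            "M_group_a": [r.mean_a for r in results],
            "SD_group_a": [r.sd_a for r in results],
            "M_group_b": [r.mean_b for r in results],
            "SD_group_b": [r.sd_b for r in results],
            "U": [r.u for r in results],
            "p": [r.p for r in results],
        }
    )


def results_to_markdown(results: list[GroupComparisonResult], label_a: str, label_b: str) -> str:
    lines = [
        f"| Variable | M ({label_a}) | SD ({label_a}) | M ({label_b}) | SD ({label_b}) | U | p |",
        "|---|---|---|---|---|---|---|",
    ]
    for r in results:
        lines.append(
            f"| {r.variable} | {r.mean_a:.2f} | {r.sd_a:.2f} | {r.mean_b:.2f} "
            f"| {r.sd_b:.2f} | {r.u:.2f} | {r.p:.3f} |"
        )
    return "\n".join(lines)
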