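"""One-way ANOVA screening of candidate indicators.

Each candidate indicator is compared between the pregnant and
non-pregnant groups with a classical (equal-variance) one-way ANOVA;
indicators with p below the significance level are selected.  A forced
list overrides the test — BMI is the canonical example: clinically
relevant, so kept even when its group means do not differ.
No multiple-testing correction is applied: the screen uses a fixed
per-indicator alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .cohort import OUTCOME, CohortTable
from .errors import ScreenError


@dataclass(frozen=True)
class ScreenResult:
    """ANOVA outcome for one candidate indicator."""

    indicator: str
    f_statistic: float
    p_value: float
    selected: bool
    reason: str  # significant | forced | rejected


def anova_f_test(values: Sequence[float], groups: Sequence[int]) -> tuple[float, float]:
    """Classical one-way ANOVA F and upper-tail p for a binary grouping.

    Degrees of freedom are (1, n-2).  Degenerate inputs where both groups
    are constant with identical means yield F = 0, p = 1 rather than an
    error; identical values with zero within-group variance but different
    means yield F = inf, p = 0.
    """
    x = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if x.shape != g.shape:
        raise ScreenError("values and groups must have equal length")
    labels = np.unique(g)
    if labels.size != 2:
        raise ScreenError("groups must contain exactly two distinct labels")
    a, b = x[g == labels[0]], x[g == labels[1]]
    if a.size == 0 or b.size == 0:
        raise ScreenError("both groups must be non-empty")
    n = x.size
    if n < 3:
        raise ScreenError("need at least 3 observations in total")

    grand = x.mean()
    ss_between = a.size * (a.mean() - grand) ** 2 + b.size * (b.mean() - grand) ** 2
    ss_within = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    df1, df2 = 1, n - 2
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f = (ss_between / df1) / (ss_within / df2)
    p = float(stats.f.sf(f, df1, df2))
    return float(f), p


def select_indicators(
    cohort: CohortTable,
    candidates: Sequence[str],
    alpha: float = 0.01,
    forced: Sequence[str] = (),
) -> list[ScreenResult]:
    """Screen candidates at ``alpha``; forced names pass regardless of p."""
    if not candidates:
        raise ScreenError("empty candidate list")
    if not 0.0 < alpha <= 1.0:
        raise ScreenError("alpha must lie in (0, 1]")
    unknown = [c for c in candidates if c not in cohort.data.columns]
    if unknown:
        raise ScreenError(f"candidates absent from cohort: {unknown}")
    forced_set = set(forced)

    outcome = cohort.outcome()
    results = []
    for name in candidates:
        f, p = anova_f_test(cohort.values(name), outcome)
        if name in forced_set:
            selected, reason = True, "forced"
        elif p < alpha:
            selected, reason = True, "significant"
        else:
            selected, reason = False, "rejected"
        results.append(ScreenResult(name, f, p, selected, reason))
    return results


def screen_report_frame(results: Sequence[ScreenResult]):
    """Tidy report of a screen (one row per candidate)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "indicator": [r.indicator for r in results],
            "F": [r.f_statistic for r in results],
            "p": [r.p_value for r in results],
            "selected": [r.selected for r in results],
            "reason": [r.reason for r in results],
        }
    )
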