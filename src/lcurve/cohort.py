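"""Group-level descriptive and contingency statistics over experience groups.

Covers the analytical surface of a registry baseline table: per-group event
proportions, Pearson chi-square over the 2xk table, the Mantel-Haenszel
linear-by-linear trend test on ordered group scores, Kruskal-Wallis for
continuous covariates, and crude (unadjusted) odds ratios between groups.
"""

from __future__ import annotations

import decimal
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupTable",
    "proportion_by_group",
    "chi_square_groups",
    "mantel_haenszel_trend",
    "kruskal_wallis_groups",
    "crude_odds_ratio",
    "round_half_up",
]


def round_half_up(x, ndigits=1):
    """Decimal half-up rounding, matching journal-table display style.

    numpy/python round half to even; printed tables round 0.05 up.
    """
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(float(x))).quantize(
        q, rounding=decimal.ROUND_HALF_UP))


@dataclass
class GroupTable:
    """Events and totals per ordered experience group (a 2xk table)."""

    group_labels: list
    totals: np.ndarray
    events: np.ndarray
    scores: np.ndarray = None
    rates: np.ndarray = field(init=False)

    def __post_init__(self):
        self.totals = np.asarray(self.totals, dtype=int)
        self.events = np.asarray(self.events, dtype=int)
        if self.scores is None:
            self.scores = np.arange(1, len(self.totals) + 1, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.totals) < 2:
            raise ValueError("need at least 2 groups")
        if np.any(self.totals <= 0):
            raise ValueError("every group total must be positive")
        if np.any(self.events > self.totals) or np.any(self.events < 0):
            raise ValueError("events must satisfy 0 <= events <= totals")
        self.rates = self.events / self.totals

    @property
    def pooled_rate(self) -> float:
        return float(self.events.sum() / self.totals.sum())

    def display_percentages(self, ndigits=1):
        """Half-up rounded percentages, as printed in a results table."""
        return [round_half_up(100.0 * r, ndigits) for r in self.rates]


def proportion_by_group(cases: pd.DataFrame, outcome_name: str,
                        group_col="experience_group") -> GroupTable:
    """Per-group event counts and rates for a binary outcome column."""
    if outcome_name not in cases.columns:
        raise ValueError(f"unknown outcome column {outcome_name!r}")
    g = cases.groupby(group_col, sort=True)[outcome_name]
    totals = g.size().to_numpy()
    events = g.sum().to_numpy()
    labels = list(g.size().index)
    return GroupTable(group_labels=labels, totals=totals, events=events)


def chi_square_groups(table: GroupTable):
    """Pearson chi-square on the 2xk events/non-events table.

    No continuity correction; df = k - 1.
    """
    obs = np.vstack([table.events, table.totals - table.events])
    if obs.sum() == 0:
        raise ValueError("empty table")
    # degenerate margin (no events anywhere, or all events): proportions are
    # identical across groups, so there is no association to test
    if np.any(obs.sum(axis=1) == 0):
        return {"statistic": 0.0, "df": len(table.totals) - 1, "p_value": 1.0}
    stat, p, df, _ = stats.chi2_contingency(obs, correction=False)
    return {"statistic": float(stat), "df": int(df), "p_value": float(p)}


def mantel_haenszel_trend(table: GroupTable):
    """Linear-by-linear association test for trend over ordered groups.

    The statistic is ``(N - 1) * r^2`` where ``r`` is the Pearson correlation
    between the group score and the binary outcome over all N subjects,
    referred to chi-square with 1 df; two-sided p.
    """
    scores, events, totals = table.scores, table.events, table.totals
    if np.ptp(scores) == 0:
        raise ValueError("trend test requires non-constant group scores")
    N = totals.sum()
    E = events.sum()
    # moments of (score, outcome) over subjects, without expansion
    sx = float(scores @ totals)
    sxx = float((scores**2) @ totals)
    sxy = float(scores @ events)
    var_x = sxx / N - (sx / N) ** 2
    var_y = E / N - (E / N) ** 2
    cov = sxy / N - (sx / N) * (E / N)
    if var_x <= 0 or var_y <= 0:
        stat = 0.0
    else:
        r2 = cov * cov / (var_x * var_y)
        stat = (N - 1) * r2
    return {"statistic": float(stat), "df": 1,
            "p_value": float(stats.chi2.sf(stat, 1))}


def kruskal_wallis_groups(cases: pd.DataFrame, continuous_field: str,
                          group_col="experience_group"):
    """Kruskal-Wallis rank test of a continuous variable across groups.

    Tie-corrected H with a chi-square(k-1) reference.  If every value is
    identical the statistic is 0 by convention (with a warning).
    """
    groups = [sub[continuous_field].dropna().to_numpy()
              for _, sub in cases.groupby(group_col, sort=True)]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 groups with >= 1 observation each")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        warnings.warn("all values tied; Kruskal-Wallis statistic set to 0")
        return {"statistic": 0.0, "df": len(groups) - 1, "p_value": 1.0}
    stat, p = stats.kruskal(*groups)
    return {"statistic": float(stat), "df": len(groups) - 1, "p_value": float(p)}


def crude_odds_ratio(table: GroupTable, ref_group, target_group):
    """Unadjusted odds ratio of target vs reference group with Woolf 95% CI.

    When any cell of the 2x2 table is zero a Haldane 0.5 continuity
    correction is applied to every cell and flagged in the result; if both
    event cells are zero the OR is undefined.
    """
    labels = list(table.group_labels)
    i, j = labels.index(ref_group), labels.index(target_group)
    a = table.events[j]                      # target events
    b = table.totals[j] - table.events[j]
    c = table.events[i]                      # reference events
    d = table.totals[i] - table.events[i]
    if a == 0 and c == 0:
        raise ValueError("both event cells are zero; odds ratio undefined")
    corrected = False
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells == 0):
        cells = cells + 0.5
        corrected = True
    a_, b_, c_, d_ = cells
    log_or = np.log(a_ * d_ / (b_ * c_))
    se = np.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    z = stats.norm.ppf(0.975)
    return {
        "odds_ratio": float(np.exp(log_or)),
        "ci_low": float(np.exp(log_or - z * se)),
        "ci_high": float(np.exp(log_or + z * se)),
        "continuity_corrected": corrected,
    }
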