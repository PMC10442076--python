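"""CUSUM trajectories, learning-curve endpoints and slope comparison.

The cumulative sum chart scores each consecutive case against a fixed
reference failure rate ``x0``: starting from ``E0 = 0``, the score gains
``1 - x0`` when the case is a failure and loses ``x0`` when it is not, so
``E_n = F(n) - n*x0`` where ``F(n)`` counts failures among the first ``n``
cases.  The chart drifts upward while the operator's failure rate exceeds the
reference and downward once it falls below it; the learning-curve endpoint is
the first case after which the chart stays at or below zero for the rest of
the observed series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "CusumTrajectory",
    "LearningCurveResult",
    "cusum_trajectory",
    "default_reference_rate",
    "learning_endpoint",
    "fit_cusum_slope",
    "compare_slopes",
    "trajectories_by_centre",
    "summarize_learning",
]

#: reference failure rates from prior published series
REFERENCE_RATES = {"major_complication": 0.15, "poor_outcome": 0.05}

#: absolute tolerance for the E_n <= 0 endpoint comparison; absorbs
#: floating-point accumulation over long series
ENDPOINT_ATOL = 1e-12


@dataclass
class CusumTrajectory:
    """One centre's CUSUM series ``E_0 .. E_N`` against reference rate x0."""

    centre_id: str
    outcome_name: str
    x0: float
    values: np.ndarray  # length N + 1, values[0] == 0

    @property
    def n_cases(self) -> int:
        return len(self.values) - 1

    @property
    def failures(self) -> np.ndarray:
        """Recover the binary outcome sequence from the increments."""
        return (np.diff(self.values) > 0).astype(int)


@dataclass
class LearningCurveResult:
    centre_id: str
    outcome_name: str
    x0: float
    n_cases: int
    endpoint: int | None
    slope: float | None = None
    intercept: float | None = None
    r_squared: float | None = None


def default_reference_rate(outcome_name: str) -> float:
    """Reference failure rate for a recognized outcome.

    0.15 for major complications and 0.05 for poor outcomes, the benchmark
    rates for endovascular aneurysm treatment this study design compares
    against.  Callers may override with any rate in (0, 1).
    """
    try:
        return REFERENCE_RATES[outcome_name]
    except KeyError:
        raise ValueError(
            f"unknown outcome {outcome_name!r}; expected one of "
            f"{sorted(REFERENCE_RATES)}") from None


def cusum_trajectory(outcomes, x0, centre_id="", outcome_name="") -> CusumTrajectory:
    """Build the CUSUM series for an ordered binary outcome sequence.

    An empty sequence yields the length-1 trajectory ``(0,)``.
    """
    if not 0.0 < x0 < 1.0:
        raise ValueError(f"x0={x0} must lie strictly in (0, 1)")
    y = np.asarray(list(outcomes), dtype=float)
    if y.size and not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcomes must be binary 0/1")
    # accumulate the failure count in integers so E_n = F(n) - n*x0 holds to
    # one rounding each, instead of letting float error build up step by step
    F = np.concatenate([[0], np.cumsum(y.astype(np.int64))])
    values = F - np.arange(len(F)) * x0
    return CusumTrajectory(centre_id=centre_id, outcome_name=outcome_name,
                           x0=float(x0), values=values)


def learning_endpoint(traj: CusumTrajectory, atol: float = ENDPOINT_ATOL):
    """First case after which the chart never rises above zero again.

    Returns the smallest ``n >= 1`` with ``E_m <= 0`` for every ``m`` from
    ``n`` through ``N`` — the case where the failure rate reaches the
    expected level or lower and stays there — or ``None`` if ``E_N > 0``.
    ``E_m = 0`` exactly counts as "at the expected level".
    """
    v = traj.values
    if len(v) < 2:
        return None
    below = v[1:] <= atol
    if not below[-1]:
        return None
    # last index (1-based) where the chart is above zero, then the next case
    above = np.flatnonzero(~below)
    return int(above[-1] + 2) if above.size else 1


def fit_cusum_slope(traj: CusumTrajectory) -> LearningCurveResult:
    """OLS of ``E_n`` on ``n`` over n = 1..N.

    The ``E_0 = 0`` anchor is a boundary condition, not an observation, and
    is excluded.  ``R^2 = 1 - SS_res/SS_tot``; a residual-free fit to a
    constant series reports ``R^2 = 1``.
    """
    N = traj.n_cases
    if N < 2:
        raise ValueError("slope fit requires at least 2 cases")
    n = np.arange(1, N + 1, dtype=float)
    y = traj.values[1:]
    slope, intercept = np.polyfit(n, y, 1)
    resid = y - (slope * n + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res < 1e-20 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return LearningCurveResult(
        centre_id=traj.centre_id, outcome_name=traj.outcome_name, x0=traj.x0,
        n_cases=N, endpoint=learning_endpoint(traj),
        slope=float(slope), intercept=float(intercept), r_squared=float(r2))


def compare_slopes(trajectories):
    """Per-centre CUSUM slopes plus an F-test of slope homogeneity.

    Fits a pooled linear model of the CUSUM score on case index with
    centre-specific intercepts, with and without centre x index interaction
    terms; the partial F-test of the interaction block tests whether all
    centres share one slope.

    Returns ``(slope_table, test)`` where ``slope_table`` is a DataFrame of
    per-centre slope fits and ``test`` a dict with ``f_statistic``,
    ``df_num``, ``df_den`` and ``p_value``.  With residual-free trajectories
    the F statistic is degenerate (0/0); it is reported as 0 with p = 1 when
    the interaction adds nothing, consistent with identical slopes.
    """
    trajectories = list(trajectories)
    if len(trajectories) < 2:
        raise ValueError("slope comparison needs at least 2 trajectories")
    rows, frames = [], []
    for i, t in enumerate(trajectories):
        res = fit_cusum_slope(t)
        rows.append(res)
        frames.append(pd.DataFrame({
            # unique label even if centre ids repeat
            "centre_id": f"t{i}_{t.centre_id}",
            "n": np.arange(1, t.n_cases + 1, dtype=float),
            "e": t.values[1:],
        }))
    table = pd.DataFrame([r.__dict__ for r in rows])
    pooled = pd.concat(frames, ignore_index=True)

    d = pd.get_dummies(pooled["centre_id"], drop_first=True, dtype=float)
    base = np.column_stack([np.ones(len(pooled)), d.to_numpy(), pooled["n"]])
    inter = d.to_numpy() * pooled["n"].to_numpy()[:, None]
    full = np.column_stack([base, inter])

    fit_r = sm.OLS(pooled["e"].to_numpy(), base).fit()
    fit_f = sm.OLS(pooled["e"].to_numpy(), full).fit()
    df_num = inter.shape[1]
    df_den = int(fit_f.df_resid)
    ssr_drop = fit_r.ssr - fit_f.ssr
    if fit_f.ssr <= 1e-12 * max(1.0, fit_r.ssr):
        # residual-free full model: F undefined; interaction either adds
        # nothing (identical slopes) or explains everything
        if ssr_drop <= 1e-12:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = np.inf, 0.0
    else:
        f_stat = max(ssr_drop, 0.0) / df_num / (fit_f.ssr / df_den)
        p = float(stats.f.sf(f_stat, df_num, df_den))
    test = {"f_statistic": float(f_stat), "df_num": df_num,
            "df_den": df_den, "p_value": float(p)}
    return table, test


def trajectories_by_centre(cases: pd.DataFrame, outcome_name: str, x0=None):
    """CUSUM trajectory per centre from a case-level frame.

    Cases are ordered by ``case_index`` within each centre; ``x0`` defaults
    to the outcome's reference rate.
    """
    if outcome_name not in cases.columns:
        raise ValueError(f"outcome column {outcome_name!r} not in cases")
    if x0 is None:
        x0 = default_reference_rate(outcome_name)
    out = []
    for centre, sub in cases.groupby("centre_id", sort=True):
        y = sub.sort_values("case_index")[outcome_name].to_numpy()
        out.append(cusum_trajectory(y, x0, centre_id=str(centre),
                                    outcome_name=outcome_name))
    return out


def summarize_learning(trajectories):
    """Slope/endpoint table plus pooled endpoint summaries.

    The pooled summary reports the mean and maximum endpoint over the
    trajectories that reach one, and how many never do.
    """
    table = pd.DataFrame([fit_cusum_slope(t).__dict__ for t in trajectories])
    reached = table["endpoint"].dropna()
    summary = {
        "n_trajectories": len(table),
        "n_reached": int(reached.size),
        "mean_endpoint": float(reached.mean()) if reached.size else None,
        "max_endpoint": int(reached.max()) if reached.size else None,
        "mean_r_squared": float(table["r_squared"].mean()),
    }
    return table, summary
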