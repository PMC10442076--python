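"""Covariate-adjusted risk models for operator experience.

Multivariable logistic regression (maximum likelihood via iteratively
reweighted least squares, through statsmodels GLM), Wald odds ratios,
restricted-cubic-spline dose-response in procedure count, a likelihood-ratio
test for nonlinearity, and an operator x experience-group interaction test.

Covariate coding
----------------
Two codings of the adjustment set are exposed:

* ``"binary"`` (default): age in years, female sex, operator (centre) as a
  categorical fixed effect, giant aneurysm (size > 25 mm) and posterior
  circulation location as binary indicators.
* ``"continuous"``: aneurysm size in mm as a continuous term and location as
  a four-level factor (ICA reference).

With only four operators, operator enters as a fixed (not random) effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

__all__ = [
    "LogisticFit",
    "SplineBasis",
    "fit_logistic",
    "build_covariate_design",
    "adjusted_group_or",
    "rcs_basis",
    "nonlinearity_lrt",
    "operator_interaction_test",
]

GIANT_SIZE_MM = 25.0
SEPARATION_EPS = 1e-10
AUTO_KNOT_QUANTILES = (0.05, 0.35, 0.65, 0.95)


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit with Wald inference."""

    params: pd.Series
    cov: pd.DataFrame
    deviance: float
    n_obs: int
    converged: bool
    iterations: int
    quasi_separation: bool = False
    dropped_columns: list = field(default_factory=list)
    fitted: np.ndarray = None

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    def odds_ratios(self, alpha=0.05) -> pd.DataFrame:
        """exp(beta) with Wald (1 - alpha) confidence intervals."""
        z = stats.norm.ppf(1 - alpha / 2)
        se = self.bse
        return pd.DataFrame({
            "odds_ratio": np.exp(self.params),
            "ci_low": np.exp(self.params - z * se),
            "ci_high": np.exp(self.params + z * se),
            "p_value": 2 * stats.norm.sf(np.abs(self.params / se)),
        })

    def wald_p(self, name: str) -> float:
        z = self.params[name] / self.bse[name]
        return float(2 * stats.norm.sf(abs(z)))


def _drop_aliased(X: pd.DataFrame):
    """Greedy left-to-right scan keeping a full-rank column subset."""
    arr = X.to_numpy(dtype=float)
    keep, dropped = [], []
    rank = 0
    basis = np.empty((len(X), 0))
    for j, col in enumerate(X.columns):
        cand = np.column_stack([basis, arr[:, j]])
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            keep.append(col)
            basis, rank = cand, r
        else:
            dropped.append(col)
    return X[keep], dropped


def fit_logistic(outcome, design_matrix: pd.DataFrame,
                 start_params=None) -> LogisticFit:
    """Fit a logistic regression by IRLS.

    The design matrix must include its own intercept column if one is
    wanted.  Aliased (collinear) columns are dropped with a warning;
    quasi-separation (any fitted probability within 1e-10 of 0 or 1) is
    flagged, in which case Wald intervals are unreliable.
    """
    y = np.asarray(outcome, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    if not isinstance(design_matrix, pd.DataFrame):
        design_matrix = pd.DataFrame(np.asarray(design_matrix))
        design_matrix.columns = [f"x{j}" for j in range(design_matrix.shape[1])]
    X, dropped = _drop_aliased(design_matrix)
    if dropped:
        warnings.warn(f"dropped aliased design columns: {dropped}")
    if len(y) <= X.shape[1]:
        raise ValueError("need more observations than predictors")

    Xa = X.to_numpy(dtype=float)
    model = sm.GLM(y, Xa, family=sm.families.Binomial())
    start = None
    if start_params is not None:
        start = pd.Series(0.0, index=X.columns)
        for k, v in dict(start_params).items():
            if k in start.index:
                start[k] = v
        start = start.to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=200, tol=1e-8, start_params=start)
    mu = np.asarray(res.mu)
    quasi = bool(np.any(mu < SEPARATION_EPS) or np.any(mu > 1 - SEPARATION_EPS))
    if quasi:
        warnings.warn("quasi-separation detected; confidence intervals unreliable")
    params = pd.Series(res.params, index=X.columns)
    cov = pd.DataFrame(np.asarray(res.cov_params()), index=X.columns,
                       columns=X.columns)
    # score (gradient of the log-likelihood) at the solution; a tiny score
    # counts as converged even if the deviance-change rule timed out
    score = Xa.T @ (y - mu)
    converged = bool(res.converged) or float(np.max(np.abs(score))) < 1e-6
    return LogisticFit(
        params=params, cov=cov, deviance=float(res.deviance),
        n_obs=len(y), converged=converged,
        iterations=int(getattr(res, "fit_history", {}).get("iteration", 0) or 0),
        quasi_separation=quasi, dropped_columns=dropped, fitted=mu)


def build_covariate_design(cases: pd.DataFrame, coding="binary",
                           include_operator=True) -> pd.DataFrame:
    """Adjustment covariate columns (no intercept, no experience terms)."""
    cols = {"age": cases["age"].to_numpy(dtype=float),
            "sex_female": cases["sex_female"].to_numpy(dtype=float)}
    if coding == "binary":
        cols["giant_aneurysm"] = (cases["aneurysm_size_mm"] > GIANT_SIZE_MM
                                  ).to_numpy(dtype=float)
        cols["posterior_location"] = (cases["location"] == "posterior"
                                      ).to_numpy(dtype=float)
        X = pd.DataFrame(cols, index=cases.index)
    elif coding == "continuous":
        cols["aneurysm_size_mm"] = cases["aneurysm_size_mm"].to_numpy(dtype=float)
        X = pd.DataFrame(cols, index=cases.index)
        loc = pd.get_dummies(pd.Categorical(cases["location"],
                                            categories=["ICA", "ACA", "MCA", "posterior"]),
                             prefix="loc", dtype=float).set_axis(cases.index)
        X = pd.concat([X, loc.drop(columns="loc_ICA")], axis=1)
    else:
        raise ValueError(f"unknown covariate coding {coding!r}")
    if include_operator:
        op = pd.get_dummies(cases["centre_id"], prefix="op", dtype=float,
                            drop_first=True).set_axis(cases.index)
        X = pd.concat([X, op], axis=1)
    return X


def _group_dummies(cases):
    g = cases["experience_group"].astype(int)
    out = pd.DataFrame(index=cases.index)
    for level in sorted(g.unique())[1:]:
        out[f"group_{level}"] = (g == level).astype(float)
    return out


def adjusted_group_or(cases: pd.DataFrame, outcome_name: str,
                      coding="binary", include_operator=True):
    """Adjusted odds ratios of each experience group vs group 1.

    Fits outcome ~ group dummies + covariates; reports Wald ORs with 95%
    CIs per group, plus a trend p from the companion model with group
    entered as an ordinal score.
    """
    y = cases[outcome_name].to_numpy(dtype=float)
    if y.sum() == 0:
        raise ValueError(f"no {outcome_name} events; odds ratios not estimable")
    Z = build_covariate_design(cases, coding, include_operator)
    const = pd.DataFrame({"const": np.ones(len(cases))}, index=cases.index)
    Xg = pd.concat([const, _group_dummies(cases), Z], axis=1)
    fit = fit_logistic(y, Xg)
    ors = fit.odds_ratios()
    group_rows = [c for c in fit.params.index if c.startswith("group_")]

    Xt = pd.concat([const, cases["experience_group"].astype(float).rename("group_score"),
                    Z], axis=1)
    fit_trend = fit_logistic(y, Xt)
    trend_p = fit_trend.wald_p("group_score")
    return {"or_table": ors.loc[group_rows], "trend_p": trend_p,
            "fit": fit, "trend_fit": fit_trend}


@dataclass
class SplineBasis:
    """Restricted cubic spline basis (truncated-power parameterization)."""

    knots: np.ndarray
    columns: pd.DataFrame  # linear term + k-2 restricted nonlinear terms

    def transform(self, x) -> pd.DataFrame:
        return _rcs_columns(np.asarray(x, dtype=float), self.knots)


def _rcs_columns(x, knots):
    t = np.asarray(knots, dtype=float)
    k = len(t)
    norm = (t[-1] - t[0]) ** 2

    def cube(u):
        return np.clip(u, 0.0, None) ** 3

    cols = {"rcs_linear": x}
    denom = t[-1] - t[-2]
    for j in range(k - 2):
        term = (cube(x - t[j])
                - cube(x - t[-2]) * (t[-1] - t[j]) / denom
                + cube(x - t[-1]) * (t[-2] - t[j]) / denom)
        cols[f"rcs_nl{j + 1}"] = term / norm
    return pd.DataFrame(cols)


def rcs_basis(x, knots="auto") -> SplineBasis:
    """Restricted cubic spline basis for the experience axis.

    With k knots the basis has k - 1 columns: the linear term plus k - 2
    nonlinear truncated-power terms, each normalized by the squared overall
    knot span so all columns share the scale of x.  The basis is constrained
    to be linear beyond the outer knots.  ``knots="auto"`` places 4 knots at
    the 0.05/0.35/0.65/0.95 quantiles of x.
    """
    x = np.asarray(x, dtype=float)
    if isinstance(knots, str) and knots == "auto":
        if len(np.unique(x)) < 5:
            raise ValueError("auto-knot placement needs >= 5 distinct x values")
        knots = np.quantile(x, AUTO_KNOT_QUANTILES)
    knots = np.asarray(knots, dtype=float)
    if len(knots) < 3:
        raise ValueError("need at least 3 knots")
    if np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly increasing")
    return SplineBasis(knots=knots, columns=_rcs_columns(x, knots))


def nonlinearity_lrt(cases: pd.DataFrame, outcome_name: str, coding="binary",
                     include_operator=True, knots="auto", curve_points=100):
    """Likelihood-ratio test of nonlinearity in the experience effect.

    Compares the adjusted logistic model with a linear procedure-count term
    against the model adding the restricted-cubic-spline nonlinear terms;
    the deviance difference is referred to chi-square with df equal to the
    number of nonlinear terms (2 for four knots).  Also returns a fitted
    risk curve (x, predicted probability, 95% band) at covariate means.
    """
    y = cases[outcome_name].to_numpy(dtype=float)
    x = cases["case_index"].to_numpy(dtype=float)
    basis = rcs_basis(x, knots)
    B = basis.columns.set_axis(cases.index)
    Z = build_covariate_design(cases, coding, include_operator)
    const = pd.DataFrame({"const": np.ones(len(cases))}, index=cases.index)

    X_lin = pd.concat([const, B[["rcs_linear"]], Z], axis=1)
    X_spl = pd.concat([const, B, Z], axis=1)
    fit_lin = fit_logistic(y, X_lin)
    # warm-start the spline model from the nested linear fit: the extra
    # nonlinear directions can be nearly flat in the likelihood, and a cold
    # IRLS start may wander along them
    fit_spl = fit_logistic(y, X_spl, start_params=fit_lin.params)
    if not (fit_lin.converged and fit_spl.converged):
        raise RuntimeError("nested fits did not both converge")
    nl_cols = [c for c in fit_spl.params.index if c.startswith("rcs_nl")]
    lrt = max(fit_lin.deviance - fit_spl.deviance, 0.0)
    df = len(nl_cols)
    p = float(stats.chi2.sf(lrt, df))

    # risk curve at covariate means over the observed experience range
    grid = np.linspace(x.min(), x.max(), curve_points)
    Bg = basis.transform(grid)
    zbar = Z.mean(axis=0)
    Xg = np.column_stack([np.ones(len(grid)), Bg.to_numpy(),
                          np.tile(zbar.to_numpy(), (len(grid), 1))])
    Xg = pd.DataFrame(Xg, columns=["const", *Bg.columns, *Z.columns])
    Xg = Xg[fit_spl.params.index]
    eta = Xg.to_numpy() @ fit_spl.params.to_numpy()
    se = np.sqrt(np.einsum("ij,jk,ik->i", Xg.to_numpy(),
                           fit_spl.cov.to_numpy(), Xg.to_numpy()))
    z = stats.norm.ppf(0.975)
    curve = pd.DataFrame({
        "case_index": grid,
        "risk": expit(eta),
        "ci_low": expit(eta - z * se),
        "ci_high": expit(eta + z * se),
    })
    return {"lrt": float(lrt), "df": df, "p_value": p,
            "fit_linear": fit_lin, "fit_spline": fit_spl, "curve": curve}


def operator_interaction_test(cases: pd.DataFrame, outcome_name: str):
    """Sensitivity LRT: does the experience effect differ between operators?

    Compares the main-effects model (experience group + operator) against
    the model adding group x operator interaction terms; df = (groups - 1) x
    (operators - 1) minus any interaction columns dropped because an
    operator has no events in any group (flagged).
    """
    ops = sorted(cases["centre_id"].unique())
    if len(ops) < 2:
        raise ValueError("interaction test needs >= 2 operators")
    y = cases[outcome_name].to_numpy(dtype=float)
    const = pd.DataFrame({"const": np.ones(len(cases))}, index=cases.index)
    G = _group_dummies(cases)
    O = pd.get_dummies(cases["centre_id"], prefix="op", dtype=float,
                       drop_first=True).set_axis(cases.index)
    X_main = pd.concat([const, G, O], axis=1)

    events_by_op = cases.groupby("centre_id")[outcome_name].sum()
    zero_ops = [op for op in ops[1:] if events_by_op[op] == 0]
    inter = {}
    for op_col in O.columns:
        op_name = op_col[len("op_"):]
        if op_name in zero_ops:
            continue
        for g_col in G.columns:
            inter[f"{g_col}:{op_col}"] = G[g_col] * O[op_col]
    X_full = pd.concat([X_main, pd.DataFrame(inter, index=cases.index)], axis=1)

    fit_main = fit_logistic(y, X_main)
    fit_full = fit_logistic(y, X_full)
    kept = [c for c in fit_full.params.index if ":" in c]
    lrt = max(fit_main.deviance - fit_full.deviance, 0.0)
    df = len(kept)
    return {"lrt": float(lrt), "df": df,
            "p_value": float(stats.chi2.sf(lrt, df)) if df else 1.0,
            "zero_event_operators": zero_ops,
            "fit_main": fit_main, "fit_interaction": fit_full}
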