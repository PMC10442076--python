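"""Logistic fits, restricted cubic splines, and the likelihood-ratio tests."""

import warnings

import numpy as np
import pandas as pd
import pytest

import lcurve as lc
from lcurve.models import rcs_basis

from conftest import make_linear_logit_cases


def brute_force_rcs(x, knots):
    """Independent truncated-power implementation of the restricted basis."""
    t = list(map(float, knots))
    k = len(t)
    span2 = (t[-1] - t[0]) ** 2

    def pos3(u):
        return max(u, 0.0) ** 3

    cols = [list(map(float, x))]
    for j in range(k - 2):
        col = []
        for xi in x:
            v = (pos3(xi - t[j])
                 - pos3(xi - t[k - 2]) * (t[k - 1] - t[j]) / (t[k - 1] - t[k - 2])
                 + pos3(xi - t[k - 1]) * (t[k - 2] - t[j]) / (t[k - 1] - t[k - 2]))
            col.append(v / span2)
        cols.append(col)
    return np.array(cols).T


class TestLogisticFit:
    def test_intercept_only_closed_form(self):
        y = np.array([1] * 7 + [0] * 13, dtype=float)
        X = pd.DataFrame({"const": np.ones(20)})
        fit = lc.fit_logistic(y, X)
        assert fit.params["const"] == pytest.approx(np.log(7 / 13), abs=1e-6)
        assert fit.converged

    def test_aliased_columns_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        n = 200
        x = rng.normal(size=n)
        X = pd.DataFrame({"const": np.ones(n), "x": x, "x2": 2 * x})
        y = (rng.random(n) < 0.3).astype(float)
        with pytest.warns(UserWarning, match="aliased"):
            fit = lc.fit_logistic(y, X)
        assert fit.dropped_columns == ["x2"]
        assert list(fit.params.index) == ["const", "x"]

    def test_perfect_separation_flagged(self):
        x = np.linspace(-2, 2, 40)
        y = (x > 0).astype(float)
        X = pd.DataFrame({"const": np.ones(40), "x": x})
        with pytest.warns(UserWarning, match="separation"):
            fit = lc.fit_logistic(y, X)
        assert fit.quasi_separation

    def test_non_binary_outcome_rejected(self):
        with pytest.raises(ValueError):
            lc.fit_logistic(np.array([0.0, 0.5]),
                            pd.DataFrame({"const": [1.0, 1.0]}))

    def test_ci_widens_as_events_get_rarer(self):
        """Wald interval for the log-odds widens monotonically over a grid
        of decreasing event counts at fixed n."""
        widths = []
        for k in (200, 80, 30, 10):
            y = np.array([1] * k + [0] * (400 - k), dtype=float)
            fit = lc.fit_logistic(y, pd.DataFrame({"const": np.ones(400)}))
            ors = fit.odds_ratios()
            widths.append(np.log(ors["ci_high"].iloc[0])
                          - np.log(ors["ci_low"].iloc[0]))
        assert all(a < b for a, b in zip(widths, widths[1:]))


class TestSplineBasis:
    def test_four_knots_give_three_columns(self):
        b = rcs_basis(np.linspace(0, 100, 50), knots=[10, 30, 60, 90])
        assert list(b.columns.columns) == ["rcs_linear", "rcs_nl1", "rcs_nl2"]

    def test_matches_brute_force_truncated_power_formula(self):
        x = np.linspace(-5, 110, 50)
        knots = [10.0, 30.0, 60.0, 90.0]
        ours = rcs_basis(x, knots=knots).columns.to_numpy()
        ref = brute_force_rcs(x, knots)
        assert np.max(np.abs(ours - ref)) < 1e-10

    def test_linear_beyond_outer_knots(self):
        """Numerical second differences vanish outside the knot span."""
        knots = [10, 30, 60, 90]
        for grid in (np.linspace(91, 200, 40), np.linspace(-60, 9.5, 40)):
            B = rcs_basis(grid, knots=knots).columns.to_numpy()
            h = grid[1] - grid[0]
            d2 = (B[2:] - 2 * B[1:-1] + B[:-2]) / h ** 2
            assert np.max(np.abs(d2)) < 1e-6

    def test_auto_knots_at_conventional_quantiles(self):
        x = np.arange(1.0, 101.0)
        b = rcs_basis(x, knots="auto")
        assert np.allclose(b.knots, np.quantile(x, [0.05, 0.35, 0.65, 0.95]))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            rcs_basis(np.array([1.0, 1.0, 2.0, 2.0]), knots="auto")
        with pytest.raises(ValueError):
            rcs_basis(np.arange(10.0), knots=[1.0, 5.0, 5.0, 9.0])


class TestAdjustedOddsRatios:
    def test_null_effects_give_unit_odds_ratios(self, covariate_cohort):
        cases = lc.simulate_logistic_outcomes(
            covariate_cohort, {"const": -1.8}, seed=21)
        adj = lc.adjusted_group_or(cases, "major_complication")
        ors = adj["or_table"]["odds_ratio"]
        assert np.all(np.abs(np.log(ors)) < 0.25)
        assert adj["trend_p"] > 0.01

    def test_recovers_generated_group_effects(self, covariate_cohort):
        """Group log-odds (0, -0.3, -2.0) at n = 10 000 come back within
        20% relative error on the odds-ratio scale."""
        cases = lc.simulate_logistic_outcomes(
            covariate_cohort,
            {"const": -1.5, "group_2": -0.3, "group_3": -2.0}, seed=13)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            adj = lc.adjusted_group_or(cases, "major_complication")
        ors = adj["or_table"]["odds_ratio"]
        assert abs(ors["group_2"] - np.exp(-0.3)) / np.exp(-0.3) < 0.2
        assert abs(ors["group_3"] - np.exp(-2.0)) / np.exp(-2.0) < 0.2
        assert adj["trend_p"] < 0.001

    def test_no_events_refused(self, plus_fixture):
        df = plus_fixture.copy()
        df["poor_outcome"] = 0
        with pytest.raises(ValueError, match="events"):
            lc.adjusted_group_or(df, "poor_outcome")


class TestNonlinearityLRT:
    def test_deviance_nesting_and_constrained_equivalence(self):
        """The spline model never fits worse than the linear model, and the
        spline design evaluated at the linear solution (nonlinear terms 0)
        reproduces the linear deviance exactly."""
        rng = np.random.default_rng(8)
        cases = make_linear_logit_cases(250, rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = lc.nonlinearity_lrt(cases, "major_complication",
                                      curve_points=10)
        assert res["lrt"] >= 0.0
        assert res["df"] == 2
        fit_lin, fit_spl = res["fit_linear"], res["fit_spline"]
        padded = pd.Series(0.0, index=fit_spl.params.index)
        padded[fit_lin.params.index] = fit_lin.params
        # deviance of the spline design at the padded linear solution
        y = cases["major_complication"].to_numpy(dtype=float)
        from lcurve.models import build_covariate_design
        basis = rcs_basis(cases["case_index"].to_numpy(dtype=float))
        X = pd.concat([
            pd.DataFrame({"const": np.ones(len(cases))}, index=cases.index),
            basis.columns.set_axis(cases.index),
            build_covariate_design(cases)], axis=1)[fit_spl.params.index]
        eta = X.to_numpy() @ padded.to_numpy()
        mu = 1 / (1 + np.exp(-eta))
        dev = -2 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu))
        assert dev == pytest.approx(fit_lin.deviance, rel=1e-9)

    def test_curve_export_shape_and_bounds(self):
        rng = np.random.default_rng(9)
        cases = make_linear_logit_cases(250, rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = lc.nonlinearity_lrt(cases, "major_complication",
                                      curve_points=40)
        curve = res["curve"]
        assert list(curve.columns) == ["case_index", "risk", "ci_low", "ci_high"]
        assert len(curve) == 40
        assert ((curve["ci_low"] <= curve["risk"])
                & (curve["risk"] <= curve["ci_high"])).all()

    def test_detects_strong_u_shaped_risk(self):
        """Strongly U-shaped risk in procedure count is flagged nonlinear."""
        rng = np.random.default_rng(17)
        cases = make_linear_logit_cases(500, rng, intercept=-3.5,
                                        curvature=3e-5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = lc.nonlinearity_lrt(cases, "major_complication",
                                      curve_points=10)
        assert res["p_value"] < 0.01


class TestOperatorInteraction:
    def test_duplicated_centre_has_zero_interaction(self):
        cfg = lc.SimulationConfig(n_centres=1, cases_per_centre=200,
                                  p_start=0.25, p_plateau=0.05, seed=3)
        c0 = lc.simulate_operator_sequence(cfg)
        c1 = c0.copy()
        c1["centre_id"] = "centre_B"
        dup = pd.concat([c0, c1], ignore_index=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = lc.operator_interaction_test(dup, "major_complication")
        assert res["lrt"] == pytest.approx(0.0, abs=1e-6)

    def test_detects_operator_with_opposite_learning(self):
        """One operator whose risk rises with experience while the others
        improve is picked up by the interaction LRT at n = 5 000."""
        detected = 0
        for r in range(5):
            cfg = lc.SimulationConfig(
                n_centres=4, cases_per_centre=1250, p_start=0.1,
                p_plateau=0.1, group_boundaries=(400, 800), seed=100 + r)
            cases = lc.simulate_operator_sequence(cfg)
            opp = (cases["centre_id"] == "centre_D").to_numpy(dtype=float)
            g2 = (cases["experience_group"] == 2).to_numpy(dtype=float)
            g3 = (cases["experience_group"] == 3).to_numpy(dtype=float)
            eta = -2.0 - 0.5 * g2 - 1.0 * g3 + opp * (1.0 * g2 + 2.0 * g3)
            rng = np.random.default_rng(200 + r)
            cases = cases.copy()
            cases["major_complication"] = (
                rng.random(len(cases)) < 1 / (1 + np.exp(-eta))).astype(int)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = lc.operator_interaction_test(cases, "major_complication")
            detected += res["p_value"] < 0.05
        assert detected >= 4

    def test_zero_event_operator_dropped_and_flagged(self, plus_fixture):
        df = plus_fixture.copy()
        mask = df["centre_id"] == "centre_B"
        df.loc[mask, "major_complication"] = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = lc.operator_interaction_test(df, "major_complication")
        assert "centre_B" in res["zero_event_operators"]
        assert all("centre_B" not in c
                   for c in res["fit_interaction"].params.index if ":" in c)

    def test_single_operator_rejected(self):
        cfg = lc.SimulationConfig(n_centres=1, cases_per_centre=50, seed=0)
        cases = lc.simulate_operator_sequence(cfg)
        with pytest.raises(ValueError):
            lc.operator_interaction_test(cases, "major_complication")
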