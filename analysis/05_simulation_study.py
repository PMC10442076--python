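"""Calibration study on simulated operators with a known learning process.

Checks, at reduced replicate counts suitable for an interactive run:
logistic coefficient bias and Wald coverage, nonlinearity-LRT size on
linear-logit cohorts, and how often the CUSUM endpoint detector lands inside
the true learning window when risk decays from 0.35 to 0.02 with scale 6.
"""

import json
import warnings
from pathlib import Path

import numpy as np

import lcurve as lc

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20230509


def main():
    OUT.mkdir(exist_ok=True)
    results = {}

    cohort = lc.simulate_operator_sequence(lc.SimulationConfig(
        n_centres=4, cases_per_centre=2500, p_start=0.1, p_plateau=0.1,
        poor_p_start=0.05, poor_p_plateau=0.05, group_boundaries=(800, 1600),
        seed=SEED))
    truth = {"const": -3.0, "group_2": -0.3, "group_3": -0.8, "age": 0.02,
             "sex_female": 0.1, "giant_aneurysm": 0.3,
             "posterior_location": 0.2}
    biases, covered, n_rep = [], 0, 50
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r in range(n_rep):
            cases = lc.simulate_logistic_outcomes(cohort, truth, seed=SEED + r)
            adj = lc.adjusted_group_or(cases, "major_complication")
            biases.append([adj["fit"].params[k] - v for k, v in truth.items()])
            row = adj["or_table"].loc["group_3"]
            covered += row["ci_low"] <= np.exp(-0.8) <= row["ci_high"]
    results["coef_bias_max_abs"] = float(np.max(np.abs(np.mean(biases, 0))))
    results["wald_coverage_group3"] = covered / n_rep
    print(f"logistic recovery ({n_rep} reps, n=10000): max |bias| "
          f"{results['coef_bias_max_abs']:.3f} log-odds, group-3 coverage "
          f"{results['wald_coverage_group3']:.2f}")

    rej, n_lrt = 0, 200
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r in range(n_lrt):
            base = lc.simulate_operator_sequence(lc.SimulationConfig(
                n_centres=4, cases_per_centre=250, p_start=0.1, p_plateau=0.1,
                seed=SEED + 10_000 + r))
            cases = lc.simulate_logistic_outcomes(
                base, {"const": -2.0, "case_index": -0.008},
                seed=SEED + 20_000 + r)
            res = lc.nonlinearity_lrt(cases, "major_complication",
                                      curve_points=5)
            rej += res["p_value"] < 0.05
    results["nonlinearity_lrt_size"] = rej / n_lrt
    print(f"nonlinearity LRT size on linear-logit data ({n_lrt} reps): "
          f"{results['nonlinearity_lrt_size']:.3f} (nominal 0.05)")

    in_win, total = 0, 0
    for r in range(100):
        cases = lc.simulate_operator_sequence(lc.SimulationConfig(
            n_centres=4, cases_per_centre=60, p_start=0.35, p_plateau=0.02,
            learning_scale=6.0, poor_p_start=0.12, poor_p_plateau=0.01,
            poor_learning_scale=6.0, seed=SEED + 30_000 + r))
        for traj in lc.trajectories_by_centre(cases, "major_complication",
                                              0.15):
            ep = lc.learning_endpoint(traj)
            total += 1
            in_win += ep is not None and ep <= 30
    results["endpoint_in_window_rate"] = in_win / total
    print(f"endpoint inside true learning window (cases 1-30): "
          f"{results['endpoint_in_window_rate']:.3f} of {total} series")

    (OUT / "simulation_study.json").write_text(json.dumps(results, indent=2))
    print(f"\nwrote {OUT / 'simulation_study.json'}")


if __name__ == "__main__":
    main()
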