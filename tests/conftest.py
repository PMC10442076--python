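import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import lcurve as lc

settings.register_profile("suite", derandomize=True, max_examples=60,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def plus_fixture():
    return lc.build_plus_fixture()


@pytest.fixture(scope="session")
def covariate_cohort():
    """10 000-case cohort with balanced experience groups.

    Outcomes are meant to be overwritten by simulate_logistic_outcomes in
    calibration tests; boundaries (800, 1600) give group sizes
    3200/3200/3600 so all three group coefficients are well identified.
    """
    cfg = lc.SimulationConfig(
        n_centres=4, cases_per_centre=2500, p_start=0.1, p_plateau=0.1,
        poor_p_start=0.05, poor_p_plateau=0.05, group_boundaries=(800, 1600),
        seed=1)
    return lc.simulate_operator_sequence(cfg)


def make_linear_logit_cases(n_per_centre, rng, intercept=-2.0, slope=-0.008,
                            curvature=0.0, centre_x=None):
    """Cohort whose outcome follows a (possibly quadratic) logit in case index.

    Shared by nonlinearity-LRT size and power checks.
    """
    n = 4 * n_per_centre
    x = np.tile(np.arange(1, n_per_centre + 1), 4)
    eta = intercept + slope * x
    if curvature:
        c = centre_x if centre_x is not None else n_per_centre / 2
        eta = intercept + curvature * (x - c) ** 2
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    return pd.DataFrame({
        "centre_id": np.repeat(["A", "B", "C", "D"], n_per_centre),
        "case_index": x,
        "major_complication": y,
        "poor_outcome": 0,
        "age": rng.normal(56, 11, n),
        "sex_female": rng.integers(0, 2, n),
        "aneurysm_size_mm": rng.lognormal(2.53, 0.5, n),
        "location": rng.choice(["ICA", "ACA", "MCA", "posterior"], n,
                               p=[0.85, 0.02, 0.04, 0.09]),
        "experience_group": lc.experience_group(x),
    })
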