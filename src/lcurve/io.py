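"""Case-level CSV reading/validation, configuration, and the full-report run.

The case CSV has one row per patient in order of surgery within each centre:

    centre_id, case_index, major_complication, poor_outcome,
    age, sex_female, aneurysm_size_mm, location, experience_group

``experience_group`` is always rederived from ``case_index`` and the
configured group boundaries; a ``discharge_mrs`` column may stand in for
``poor_outcome`` (derived as mRS > 2).
"""

from __future__ import annotations

import dataclasses
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort, cusum, models
from .simulate import CASE_COLUMNS, LOCATIONS, experience_group

__all__ = ["AnalysisConfig", "ValidationReport", "read_cases", "write_cases",
           "run_report"]

REQUIRED_COLUMNS = ("centre_id", "case_index")
OUTCOME_COLUMNS = ("major_complication", "poor_outcome")
MRS_POOR_THRESHOLD = 2  # poor outcome = discharge mRS > 2


@dataclass
class AnalysisConfig:
    """Run configuration with auditable defaults.

    x0 values are the reference failure rates the CUSUM charts score
    against; group boundaries 10 and 20 define experience groups 1-10,
    11-20, >20.
    """

    x0_major: float = 0.15
    x0_poor: float = 0.05
    group_boundaries: tuple = (10, 20)
    covariate_coding: str = "binary"
    seed: int = 0

    def __post_init__(self):
        b = tuple(int(x) for x in self.group_boundaries)
        if len(b) < 1 or any(x <= 0 for x in b) or any(np.diff(b) <= 0):
            raise ValueError("group boundaries must be strictly increasing positive integers")
        self.group_boundaries = b
        for name in ("x0_major", "x0_poor"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} must lie in (0, 1)")

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        """Load from a plain key=value text file (or YAML-style ':')."""
        kwargs = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sep = "=" if "=" in line else ":"
            key, _, val = line.partition(sep)
            key, val = key.strip(), val.strip()
            if key in ("x0_major", "x0_poor"):
                kwargs[key] = float(val)
            elif key == "seed":
                kwargs[key] = int(val)
            elif key == "group_boundaries":
                kwargs[key] = tuple(int(x) for x in val.replace(",", " ").split())
            elif key == "covariate_coding":
                kwargs[key] = val
        return cls(**kwargs)

    def x0_for(self, outcome_name: str) -> float:
        return {"major_complication": self.x0_major,
                "poor_outcome": self.x0_poor}[outcome_name]


@dataclass
class ValidationReport:
    n_rows_read: int = 0
    n_rows_kept: int = 0
    n_rows_dropped: int = 0
    messages: list = field(default_factory=list)

    def note(self, msg):
        self.messages.append(str(msg))


def read_cases(path, config: AnalysisConfig | None = None):
    """Read and validate a case-level CSV.

    Returns ``(cases, report)``.  Missing required columns and duplicate
    (centre, case_index) pairs are hard errors; rows with unparseable or
    non-binary outcomes are dropped and counted in the report.  A
    ``discharge_mrs`` column is converted to the ``poor_outcome`` flag
    (mRS > 2) when that flag is absent.
    """
    config = config or AnalysisConfig()
    report = ValidationReport()
    df = pd.read_csv(path)
    report.n_rows_read = len(df)

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    if "poor_outcome" not in df.columns and "discharge_mrs" in df.columns:
        df["poor_outcome"] = (pd.to_numeric(df["discharge_mrs"], errors="coerce")
                              > MRS_POOR_THRESHOLD).astype(int)
        report.note(f"poor_outcome derived from discharge_mrs > {MRS_POOR_THRESHOLD}")
    outcome_missing = [c for c in OUTCOME_COLUMNS if c not in df.columns]
    if outcome_missing:
        raise ValueError(f"missing outcome columns: {outcome_missing}")

    df["case_index"] = pd.to_numeric(df["case_index"], errors="coerce")
    bad_idx = df["case_index"].isna() | (df["case_index"] < 1) \
        | (df["case_index"] != df["case_index"].astype("Int64").astype(float))
    if bad_idx.any():
        report.note(f"dropped {int(bad_idx.sum())} rows with invalid case_index")
        df = df[~bad_idx]
    df["case_index"] = df["case_index"].astype(int)

    dup = df.duplicated(subset=["centre_id", "case_index"], keep=False)
    if dup.any():
        pairs = df.loc[dup, ["centre_id", "case_index"]].drop_duplicates()
        raise ValueError("duplicate (centre_id, case_index) pairs: "
                         + "; ".join(f"{r.centre_id}/{r.case_index}"
                                     for r in pairs.itertuples()))

    for col in OUTCOME_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~vals.isin([0, 1])
        if bad.any():
            report.note(f"dropped {int(bad.sum())} rows with non-binary {col}")
            df = df[~bad]
            vals = vals[~bad]
        df[col] = vals.astype(int)

    if "location" in df.columns:
        bad_loc = df["location"].notna() & ~df["location"].isin(LOCATIONS)
        if bad_loc.any():
            report.note(f"dropped {int(bad_loc.sum())} rows with unknown location")
            df = df[~bad_loc]

    df = df.copy()
    df["experience_group"] = experience_group(df["case_index"].to_numpy(),
                                              config.group_boundaries)
    df = df.sort_values(["centre_id", "case_index"]).reset_index(drop=True)
    report.n_rows_kept = len(df)
    report.n_rows_dropped = report.n_rows_read - len(df)
    return df, report


def write_cases(cases: pd.DataFrame, path):
    """Write a case-level CSV in canonical column order (extras appended)."""
    cols = [c for c in CASE_COLUMNS if c in cases.columns]
    cols += [c for c in cases.columns if c not in cols]
    cases[cols].to_csv(path, index=False, na_rep="")


def run_report(cases: pd.DataFrame, config: AnalysisConfig, out_dir):
    """Run the full pipeline on a cohort and write a report bundle.

    Stages: group proportions + chi-square + trend per outcome; per-centre
    CUSUM trajectories, endpoints, slopes and the slope-homogeneity test;
    crude and adjusted odds ratios; spline nonlinearity test with the fitted
    risk curve; operator interaction test.  A failing stage is recorded in
    the bundle and later stages still run.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = {"config": dataclasses.asdict(config), "stages": {}}

    def stage(name, fn):
        try:
            fn()
            bundle["stages"][name] = "ok"
        except Exception as exc:  # keep earlier outputs on failure
            bundle["stages"][name] = f"failed: {exc}"
            print(f"[lcurve] stage {name} failed: {exc}", file=sys.stderr)

    def _groups():
        rows = []
        for oc in OUTCOME_COLUMNS:
            t = cohort.proportion_by_group(cases, oc)
            chi = cohort.chi_square_groups(t)
            trend = cohort.mantel_haenszel_trend(t)
            for lbl, tot, ev, pct in zip(t.group_labels, t.totals, t.events,
                                         t.display_percentages()):
                rows.append({"outcome": oc, "group": lbl, "n": int(tot),
                             "events": int(ev), "pct": pct,
                             "chi2_p": chi["p_value"],
                             "trend_p": trend["p_value"]})
            rows.append({"outcome": oc, "group": "pooled",
                         "n": int(t.totals.sum()), "events": int(t.events.sum()),
                         "pct": cohort.round_half_up(100 * t.pooled_rate),
                         "chi2_p": chi["p_value"], "trend_p": trend["p_value"]})
        pd.DataFrame(rows).to_csv(out / "group_stats.csv", index=False)

    def _cusum():
        traj_rows, summaries = [], []
        for oc in OUTCOME_COLUMNS:
            trajs = cusum.trajectories_by_centre(cases, oc, config.x0_for(oc))
            for t in trajs:
                for n, e in enumerate(t.values):
                    traj_rows.append({"outcome": oc, "centre_id": t.centre_id,
                                      "n": n, "e_n": e})
            table, summary = cusum.summarize_learning(trajs)
            _, test = cusum.compare_slopes(trajs)
            table["slope_homogeneity_p"] = test["p_value"]
            summaries.append(table)
        pd.DataFrame(traj_rows).to_csv(out / "cusum_trajectories.csv", index=False)
        pd.concat(summaries).to_csv(out / "cusum_summary.csv", index=False)

    def _odds():
        rows = []
        for oc in OUTCOME_COLUMNS:
            t = cohort.proportion_by_group(cases, oc)
            for target in t.group_labels[1:]:
                crude = cohort.crude_odds_ratio(t, t.group_labels[0], target)
                rows.append({"outcome": oc, "group": target, "type": "crude",
                             **{k: crude[k] for k in ("odds_ratio", "ci_low", "ci_high")}})
            adj = models.adjusted_group_or(cases, oc, config.covariate_coding)
            for name, r in adj["or_table"].iterrows():
                rows.append({"outcome": oc, "group": int(name.split("_")[1]),
                             "type": "adjusted", "odds_ratio": r["odds_ratio"],
                             "ci_low": r["ci_low"], "ci_high": r["ci_high"],
                             "p_value": r["p_value"], "trend_p": adj["trend_p"]})
        pd.DataFrame(rows).to_csv(out / "odds_ratios.csv", index=False)

    def _spline():
        rows = []
        for oc in OUTCOME_COLUMNS:
            res = models.nonlinearity_lrt(cases, oc, config.covariate_coding)
            res["curve"].assign(outcome=oc).to_csv(
                out / f"risk_curve_{oc}.csv", index=False)
            rows.append({"outcome": oc, "lrt": res["lrt"], "df": res["df"],
                         "p_nonlinearity": res["p_value"]})
        pd.DataFrame(rows).to_csv(out / "nonlinearity.csv", index=False)

    def _interaction():
        rows = []
        for oc in OUTCOME_COLUMNS:
            res = models.operator_interaction_test(cases, oc)
            rows.append({"outcome": oc, "lrt": res["lrt"], "df": res["df"],
                         "p_value": res["p_value"],
                         "zero_event_operators": ";".join(res["zero_event_operators"])})
        pd.DataFrame(rows).to_csv(out / "operator_interaction.csv", index=False)

    stage("group_stats", _groups)
    stage("cusum", _cusum)
    stage("odds_ratios", _odds)
    stage("nonlinearity", _spline)
    stage("operator_interaction", _interaction)

    bundle["n_cases"] = int(len(cases))
    bundle["versions"] = {"python": sys.version.split()[0],
                          "numpy": np.__version__, "pandas": pd.__version__}
    (out / "run_metadata.json").write_text(json.dumps(bundle, indent=2))
    return bundle
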