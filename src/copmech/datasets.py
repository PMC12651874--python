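"""Bundled reference data.

The cohort demographics table (18 subjects: 6 PD controls, 6 PD
intervention, 6 healthy) is the one part of the target study published
in full, and anchors the demographic summary statistics: per-group mean
and SD of age and BMI, Welch p-values for the group contrasts, and the
BMI effect size.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

from .stats import cohens_d, welch_t_test

__all__ = ["load_cohort_demographics", "demographic_summary"]


def load_cohort_demographics() -> pd.DataFrame:
    """The published cohort table: subject_id, group, sex, age, BMI."""
    ref = importlib.resources.files("copmech") / "data" / "cohort_demographics.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def demographic_summary(df: pd.DataFrame | None = None) -> dict:
    """Group means/SDs and Welch tests in the shape of a cohort summary table."""
    if df is None:
        df = load_cohort_demographics()
    out: dict = {"groups": {}, "tests": {}, "effect_sizes": {}}
    for g, sub in df.groupby("group"):
        out["groups"][g] = {
            "n": int(len(sub)),
            "age_mean": float(sub["age"].mean()),
            "age_sd": float(sub["age"].std(ddof=1)),
            "bmi_mean": float(sub["bmi"].mean()),
            "bmi_sd": float(sub["bmi"].std(ddof=1)),
            "n_male": int((sub["sex"] == "M").sum()),
            "n_female": int((sub["sex"] == "F").sum()),
        }
    ctrl = df[df.group == "pd_control"]
    tpei = df[df.group == "pd_tpei"]
    pd_all = df[df.group.isin(["pd_control", "pd_tpei"])]
    healthy = df[df.group == "healthy"]
    for feat in ("bmi", "age"):
        out["tests"][f"{feat}_control_vs_tpei"] = welch_t_test(
            ctrl[feat], tpei[feat])
        out["tests"][f"{feat}_pd_vs_healthy"] = welch_t_test(
            pd_all[feat], healthy[feat])
        out["effect_sizes"][f"{feat}_control_vs_tpei"] = cohens_d(
            ctrl[feat], tpei[feat])
    return out
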