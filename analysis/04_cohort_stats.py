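"""Run the cohort statistics battery on the measured imaging metrics.

Merges the measured ALPS and PVS tables onto the cohort covariates and
runs the full chain: demographics, age-adjusted ANCOVA group
comparisons, correlations, and the NfL multiple regression in the TBI
group. Writes results/report.json and results/report.md.
"""

import json

import pandas as pd
from _study import RESULTS

from dtialps.stats import group_compare, report_markdown


def main():
    truth = pd.read_csv(RESULTS / "cohort_truth.csv")
    alps = pd.read_csv(RESULTS / "alps_measurements.csv")
    pvs = pd.read_csv(RESULTS / "pvs_measurements.csv")
    table = (
        truth.drop(columns=["alps_mean", "pvs_volume", "pvs_count", "pvs_score"])
        .merge(alps, on="subject_id")
        .merge(pvs, on="subject_id")
    )
    report = group_compare(table)
    (RESULTS / "report.json").write_text(json.dumps(report, indent=2))
    (RESULTS / "report.md").write_text(report_markdown(report))

    a = report["ancova"]["alps_mean"]
    print(
        f"ALPS ANCOVA: group F(1,{a['df'][1]}) = {a['f_group']:.3f}, p = {a['p_group']:.3g}; "
        f"age F = {a['f_age']:.3f}, p = {a['p_age']:.3g}"
    )
    print(
        "adjusted ALPS means: "
        + ", ".join(f"{k} {v:.3f}" for k, v in a["adjusted_means"].items())
    )
    reg = report["nfl_regression"]
    print(
        f"NfL regression (TBI, n={reg['n']}): R² = {reg['r_squared']:.3f}, "
        f"F = {reg['f_overall']:.3f}, p = {reg['p_overall']:.3g}"
    )
    for name, c in reg["coefficients"].items():
        print(f"  {name}: standardized b = {c['b_std']:+.3f}, p = {c['p']:.3g}")
    print(f"wrote {RESULTS / 'report.json'} and report.md")


if __name__ == "__main__":
    main()
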