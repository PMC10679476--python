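"""Apply the inclusion/exclusion cascade and measurement cleaning.

Runs the 13-step attrition process on the simulated encounter table, then the
daily mean-vs-minimum diagnostic, same-day averaging, and the +/-5 Z-score
plausibility screen (against a preliminary constant-SD model fitted on the
unfiltered rows).

Writes results/analysis/analysis_rows.csv and attrition.csv.
"""

from pathlib import Path

from bpref.cohort import build_cohort, mean_vs_min_diagnostic
from bpref.synthetic import read_encounters

OUT = Path("results/analysis")


def main() -> None:
    table = read_encounters(OUT / "cohort_raw.csv")
    diag = mean_vs_min_diagnostic(table)
    print(f"mean > min on {diag.fraction_mean_gt_min:.1%} of {diag.n_days} BP days "
          f"(max |mean-min|: sbp {diag.max_abs_diff_sbp:.1f}, dbp {diag.max_abs_diff_dbp:.1f} mmHg);"
          " averages are used downstream")

    rows, report, removed = build_cohort(table)
    print("\nattrition cascade:")
    for line in report.log_lines():
        print(" ", line)
    print(f"\nplausibility screen removed {len(removed)} child-days (|Z| > 5)")
    print(f"analysis rows: {len(rows)} child-days, {rows.child_id.nunique()} children")

    rows.to_csv(OUT / "analysis_rows.csv", index=False)
    report.to_csv(OUT / "attrition.csv")
    print(f"wrote {OUT / 'analysis_rows.csv'} and {OUT / 'attrition.csv'}")


if __name__ == "__main__":
    main()
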