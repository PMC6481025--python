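#!/usr/bin/env python
"""Run the full group-comparison and regression analysis on the cohort.

Aggregates segment metrics to one value per subject x site, then runs
per-site FD-vs-control and male-vs-female Mann-Whitney tests for each
index, regressions on age / GFR / wall thickness, and the per-metric
conjunctiva-on-retina regression (alpha = 0.05, no multiplicity
correction). Writes results/cohort/report.json and tests.csv.
"""

from pathlib import Path

from ocutort.io import read_metrics, read_subjects
from ocutort.stats import StatsConfig, run_study

BASE = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main() -> None:
    metrics = read_metrics(BASE / "metrics.csv")
    records = read_subjects(BASE / "subjects.csv")
    report = run_study(metrics, records, StatsConfig())
    (BASE / "report.json").write_text(report.to_json())
    frame = report.tests_frame()
    frame.to_csv(BASE / "tests.csv", index=False)

    groups = frame[frame.comparison == "FD_vs_control"]
    print(f"{len(frame)} comparisons -> {BASE}/tests.csv")
    print("\nFD vs control (Mann-Whitney, two-sided):")
    for _, r in groups.iterrows():
        star = " *" if r.significant else ""
        print(f"  {r['site']:>14} {r['metric']:>4}: p = {r.p_value:.4f}{star}")
    sig_sites = sorted(groups[groups.significant]["site"].unique())
    print(f"\nsignificant group differences at: {', '.join(sig_sites)}")


if __name__ == "__main__":
    main()
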