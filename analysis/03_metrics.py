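#!/usr/bin/env python
"""Compute SOAM, PAD and I2e for every simulated vessel segment.

Reads results/cohort/traces.csv (from 01_simulate.py), resamples every
centerline to 5 px arc-length spacing and computes the three tortuosity
indexes. Writes results/cohort/metrics.csv.
"""

from pathlib import Path

import pandas as pd

from ocutort.io import read_subjects, read_traces, write_metrics
from ocutort.metrics import MetricConfig, compute_all

BASE = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main() -> None:
    traces = read_traces(BASE / "traces.csv")
    records = {r.subject_id: r for r in read_subjects(BASE / "subjects.csv")}
    cfg = MetricConfig()
    rows = []
    for key, pts in traces.items():
        sid, eye, site, seg = key.split("__")
        r = records[sid]
        rows.append(
            compute_all(pts, cfg, subject_id=sid, group=r.group, sex=r.sex,
                        age=r.age, eye=eye, site=site, segment_id=seg).as_dict()
        )
    df = pd.DataFrame(rows)
    write_metrics(BASE / "metrics.csv", df)
    print(f"{len(df)} segment metrics -> {BASE}/metrics.csv")
    print(df.groupby(["group", "site"])[["soam", "pad", "i2e"]].mean().round(4))


if __name__ == "__main__":
    main()
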