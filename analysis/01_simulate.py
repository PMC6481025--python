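#!/usr/bin/env python
"""Simulate the study cohort: 11 affected (FD) + 11 control subjects.

Generates per-subject vessel centerlines for both eyes at the retina and
the four conjunctival sectors (5 + 4x3 segments per eye), with a 2x
amplitude effect at the retina and nasal conjunctiva in the FD group.
Writes subjects.csv and traces.csv under results/cohort/.
"""

from pathlib import Path

from ocutort.io import write_subjects, write_traces
from ocutort.synth import CohortParams, gen_cohort

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cp = CohortParams(rng_seed=20190410)
    records, traces = gen_cohort(cp)
    write_subjects(OUT / "subjects.csv", records)
    write_traces(OUT / "traces.csv", {"__".join(k): v for k, v in traces.items()})
    n_fd = sum(r.group == "FD" for r in records)
    print(f"simulated {len(records)} subjects ({n_fd} FD, {len(records) - n_fd} control)")
    print(f"{len(traces)} vessel segments -> {OUT}/traces.csv")


if __name__ == "__main__":
    main()
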