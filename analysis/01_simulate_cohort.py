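#!/usr/bin/env python
"""Simulate the study cohort: treadmill calibration data for 42 subjects and
paired right/left-hip sessions for the 22-subject two-accelerometer subsample.

Writes stage tables and hidden truth under results/synthetic/.
"""

import sys
from pathlib import Path

import pandas as pd

from accelcal.cli import sessions_to_csv
from accelcal.synthetic_data import (
    CohortScenario,
    generate_calibration_cohort,
    generate_two_hip_pair,
)

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "synthetic"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 172


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    scen = CohortScenario()  # published cohort statistics, n = 42
    sessions, truth = generate_calibration_cohort(scen, seed=SEED)
    sessions_to_csv(sessions, OUT / "calibration_stages.csv")
    truth.to_csv(OUT / "calibration_truth.csv", index=False)
    print(f"calibration cohort: {len(sessions)} subjects, "
          f"true ICP mean {truth['true_icp'].mean():.0f} "
          f"(SD {truth['true_icp'].std():.0f}) counts/min")

    hip_scen = CohortScenario(n_subjects=22)
    pairs, hip_truth = generate_two_hip_pair(hip_scen, seed=SEED + 1)
    rows = []
    for right, left in pairs:
        for placement, ses in (("right_hip", right), ("left_hip", left)):
            for st in ses.stages:
                rows.append({"subject_id": ses.subject_id, "placement": placement,
                             "resting_vo2": ses.resting_vo2, "speed": st.speed,
                             "vo2": st.vo2, "counts_per_min": st.counts_per_min})
    pd.DataFrame(rows).to_csv(OUT / "two_hip_stages.csv", index=False)
    hip_truth.to_csv(OUT / "two_hip_truth.csv", index=False)
    print(f"two-hip subsample: {len(pairs)} subjects "
          f"(expected between-hip SEM ~ {hip_scen.expected_hip_sem():.0f} counts/min)")


if __name__ == "__main__":
    main()
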