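#!/usr/bin/env python
"""Quick-look calibration and power summary (scaled-down).

A reduced rendition of the experiments in scripts/acceptance.py: 40 null
cohorts for type-I error, 10 planted runs each for high- and low-rate
recovery. Useful as a fast sanity check; the acceptance script runs the
full-size versions.
"""

import json
from pathlib import Path

from transgen_scan.experiments import (
    PLANT_HIGH,
    PLANT_LOW,
    recovery_experiment,
    type1_calibration,
)

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 99


def main() -> None:
    cal = type1_calibration(n_cohorts=40, n_case_children=100, seed=SEED)
    high = recovery_experiment(n_runs=10, n_case_children=600, seed=SEED,
                               planted=PLANT_HIGH, direction="high")
    low = recovery_experiment(n_runs=10, n_case_children=600, seed=SEED,
                              planted=PLANT_LOW, direction="low")
    summary = {
        "type1_stratum_rate": round(cal["frac_strata_sig"], 4),
        "type1_n_strata": cal["n_strata"],
        "type1_familywise_rate": round(cal["frac_cohorts_familywise"], 4),
        "high_detection_rate": high["detection_rate"],
        "high_empirical_risk_ratio": round(high["median_empirical_ratio"], 3),
        "high_rr_ratio_to_truth": round(high["median_rr_ratio"], 3),
        "low_detection_rate": low["detection_rate"],
        "low_empirical_risk_ratio": round(low["median_empirical_ratio"], 3),
    }
    ROOT.mkdir(exist_ok=True)
    with open(ROOT / "calibration_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
        fh.write("\n")
    for k, v in summary.items():
        print(f"{k}: {v}")


if __name__ == "__main__":
    main()
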