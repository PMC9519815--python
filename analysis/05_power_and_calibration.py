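#!/usr/bin/env python
"""Power analysis and a reduced calibration sweep.

Computes the exact power of the one-sample t-test against chance at the
published effect size (d = 4.37, n = 30), then runs scaled-down versions of
the calibration experiments (the acceptance script runs the full-size ones):
ideal-learner ceiling, null-intercept Wald coverage, parameter recovery, and
RT-filter recall.  Writes results/calibration.json.
"""

import json
from pathlib import Path

from cswlkit.analysis import PowerSpec, power_one_sample_t
from cswlkit.calibration import (
    ideal_learner_accuracy,
    intercept_coverage,
    parameter_recovery,
    rt_filter_recall,
)

OUT = Path("results")


def main() -> None:
    power = power_one_sample_t(PowerSpec(effect_size_d=4.37, n=30, alpha=0.05))
    print(f"power at d=4.37, n=30, alpha=.05: {power:.4f} (>0.80)")
    results = {
        "power": power,
        "ideal_learner": ideal_learner_accuracy(n_seeds=25, base_seed=0),
        "intercept_coverage": intercept_coverage(n_reps=100, n_participants=12, base_seed=0),
        "parameter_recovery": parameter_recovery(n_cohorts=20, n_participants=60, base_seed=0),
        "rt_filter": rt_filter_recall(n_participants=30, seed=0),
    }
    OUT.mkdir(exist_ok=True)
    (OUT / "calibration.json").write_text(json.dumps(results, indent=2), encoding="utf-8")
    for key in ("ideal_learner", "intercept_coverage", "parameter_recovery", "rt_filter"):
        print(key, "->", json.dumps(results[key]))


if __name__ == "__main__":
    main()
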