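#!/usr/bin/env python
"""Generate and validate the cross-situational word-learning trial structure.

Emits the 36 interleaved 2x2 training trials (18 per set) and the 24 4AFC
test trials (+2 warm-ups), then prints the validation report: co-occurrence
separability (6 on the diagonal vs at most 2 off it, 0 across sets) is what
makes the mappings learnable from ambiguous trials.
"""

import json
from pathlib import Path

from cswlkit.config import load_config
from cswlkit.pipeline import run_stage

OUT = Path("results")


def main() -> None:
    cfg = load_config(None, {"out_dir": str(OUT / "pipeline"), "seed": 1})
    run_stage("design", cfg)
    report = json.loads((OUT / "pipeline" / "design_report.json").read_text())
    print(f"training trials: {report['n_training']} ({report['trials_per_set']})")
    print(f"test trials: {report['n_test']}; trial duration {report['trial_duration_ms']} ms")
    print(
        f"co-occurrence: diagonal {report['diagonal_min']}, "
        f"within-set max {report['within_set_offdiag_max']}, "
        f"cross-set max {report['cross_set_max']}"
    )
    print(f"violations: {report['violations'] or 'none'}")


if __name__ == "__main__":
    main()
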