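#!/usr/bin/env python
"""Build the two phonotactically controlled stimulus sets.

Computes positional biphone probabilities from the bundled synthetic CV
lexicon, searches CVCV pseudoword candidates, selects the six highest-PP
novel words (PP+), and recombines their syllables into six slightly
lower-PP words (PP-).  Also averages the published per-word PP values as the
printed reference points (0.0085 / 0.0073).
"""

from pathlib import Path

from cswlkit import reference
from cswlkit.config import load_config
from cswlkit.phonotactics import set_mean_pp
from cswlkit.pipeline import run_stage
from cswlkit.pseudowords import read_stimulus_sets

OUT = Path("results")


def main() -> None:
    cfg = load_config(None, {"out_dir": str(OUT / "pipeline"), "seed": 1})
    run_stage("phonotactics", cfg)
    run_stage("genwords", cfg)
    sets = read_stimulus_sets(OUT / "pipeline" / "stimuli.tsv")
    for label, rows in sorted(sets.items(), reverse=True):
        mean = set_mean_pp([pp for _, _, pp in rows])
        words = ", ".join("".join(ph) for _, ph, _ in rows)
        print(f"{label}: mean PP = {mean:.5f}  [{words}]")
    plus = set_mean_pp([pp for _, pp in reference.words("PP_plus")])
    minus = set_mean_pp([pp for _, pp in reference.words("PP_minus")])
    print(f"published stimulus table set means: PP+ {plus:.4f}, PP- {minus:.4f}")


if __name__ == "__main__":
    main()
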