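"""Simulated learners and cohorts.

Two simulators make the pipeline testable without data collection:

* ``associative`` — a mechanism-level co-occurrence learner that accumulates a
  word x object count matrix over training and answers test probes by a
  softmax over the four displayed objects' counts (temperature 0 = argmax;
  an optional lapse rate mixes in uniform guessing).
* ``glmm_generative`` — the generative counterpart of the analysis model:
  P(correct) = expit(logit(0.25) + beta0 + delta * [set = PP+] + u_p + u_s)
  with participant and stimulus random intercepts u_p ~ N(0, tau_p^2),
  u_s ~ N(0, tau_s^2); incorrect choices fall uniformly on the three foils.

Reaction times are lognormal with a uniform far-tail contamination component
emulating attentional lapses; the default 2% rate matches the share of trials
the published study excluded by its 3-SD rule.  Neither simulator is a claim
about human learning; they exist so that design validity, the RT filter, and
GLMM parameter recovery can be tested end to end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .design import Design, TestTrial, TrainingTrial
from .lexicon import LexiconEntry, PhonemeInventory, bp_inventory
from .pseudowords import PP_PLUS

RESPONSE_COLUMNS = [
    "participant_id", "trial_index", "set_label", "repetition", "probe_word",
    "chosen_object", "correct", "rt_ms", "contaminated",
]


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class ParticipantConfig:
    """Generative settings for one simulated cohort.

    beta0/delta_pp_plus are log-odds relative to chance; taus are random-effect
    SDs on the logit scale; RT parameters are on the log-ms scale, with
    contamination drawn uniformly from ``contamination_range_ms``.
    """

    learner: Literal["guesser", "associative", "glmm_generative"] = "glmm_generative"
    softmax_temperature: float = 0.5
    lapse_rate: float = 0.0
    # defaults emulate the published full-dataset fit: intercept odds 7.61,
    # PP+ odds ratio 1.19, participant/stimulus variances 2.35 and 0.21
    beta0: float = 2.03
    delta_pp_plus: float = 0.17
    tau_participant: float = 1.53
    tau_stimulus: float = 0.46
    rt_log_mean: float = 7.0  # exp(7.0) ~ 1097 ms median
    rt_log_sd: float = 0.3
    contamination_rate: float = 0.02
    contamination_range_ms: tuple[float, float] = (15000.0, 40000.0)
    chance: float = 0.25

    def __post_init__(self) -> None:
        if self.softmax_temperature < 0:
            raise SimulationError("softmax_temperature must be >= 0")
        if not 0 <= self.lapse_rate <= 1:
            raise SimulationError("lapse_rate must be in [0, 1]")
        if self.tau_participant < 0 or self.tau_stimulus < 0:
            raise SimulationError("random-effect SDs must be >= 0")
        if not 0 <= self.contamination_rate <= 1:
            raise SimulationError("contamination_rate must be in [0, 1]")
        lo, hi = self.contamination_range_ms
        if not 0 < lo <= hi:
            raise SimulationError("contamination_range_ms must be positive and ordered")


def train_associative(trials: Sequence[TrainingTrial]) -> pd.DataFrame:
    """Word x object co-occurrence counts: +1 for every word-object pair that
    shares a training trial (both words co-occur with both objects)."""
    words = sorted({w for t in trials for w in (t.first_word, t.second_word)})
    objects = sorted({o for t in trials for o in (t.left_object, t.right_object)})
    m = pd.DataFrame(0, index=words, columns=objects, dtype=int)
    for t in trials:
        for w in (t.first_word, t.second_word):
            for o in (t.left_object, t.right_object):
                m.loc[w, o] += 1
    return m


def choose_at_test(
    matrix: pd.DataFrame,
    trial: TestTrial,
    config: ParticipantConfig,
    rng: np.random.Generator,
) -> str:
    """Softmax choice over the four displayed objects' co-occurrence counts
    with the probe word; lapse_rate mixes in a uniform guess."""
    if trial.probe_word not in matrix.index:
        raise SimulationError(f"word {trial.probe_word} missing from matrix")
    for o in trial.objects:
        if o not in matrix.columns:
            raise SimulationError(f"object {o} missing from matrix")
    counts = matrix.loc[trial.probe_word, list(trial.objects)].to_numpy(dtype=float)
    if config.softmax_temperature == 0:
        best = counts == counts.max()
        probs = best / best.sum()
    else:
        z = (counts - counts.max()) / config.softmax_temperature
        e = np.exp(z)
        probs = e / e.sum()
    probs = (1 - config.lapse_rate) * probs + config.lapse_rate / 4.0
    return trial.objects[int(rng.choice(4, p=probs))]


def _draw_rts(
    n: int, config: ParticipantConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    rt = np.exp(rng.normal(config.rt_log_mean, config.rt_log_sd, size=n))
    contaminated = rng.random(n) < config.contamination_rate
    lo, hi = config.contamination_range_ms
    rt[contaminated] = rng.uniform(lo, hi, size=int(contaminated.sum()))
    return rt, contaminated


def simulate_cohort(
    design: Design,
    n_participants: int,
    config: ParticipantConfig,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate test responses for a cohort; returns the response table
    (one row per participant x test trial, RESPONSE_COLUMNS schema)."""
    if n_participants < 1:
        raise SimulationError("need at least one participant")
    rng = np.random.default_rng(seed)
    referent = design.referent_of
    rows: list[dict] = []

    if config.learner == "glmm_generative":
        from scipy.special import expit, logit

        pair_ids = [p.pair_id for p in design.pairs]
        u_s = dict(zip(pair_ids, rng.normal(0.0, config.tau_stimulus, len(pair_ids))))
        u_p = rng.normal(0.0, config.tau_participant, n_participants)
        base = logit(config.chance)
        for i in range(n_participants):
            rt, contam = _draw_rts(len(design.test), config, rng)
            for j, t in enumerate(design.test):
                eta = (
                    base
                    + config.beta0
                    + (config.delta_pp_plus if t.set_label == PP_PLUS else 0.0)
                    + u_p[i]
                    + u_s[t.probe_word]
                )
                target = referent[t.probe_word]
                if rng.random() < expit(eta):
                    chosen = target
                else:
                    foils = [o for o in t.objects if o != target]
                    chosen = foils[int(rng.integers(3))]
                rows.append(
                    _row(i, t, chosen, target, rt[j], bool(contam[j]))
                )
    elif config.learner in ("associative", "guesser"):
        matrix = train_associative(design.training)
        for i in range(n_participants):
            rt, contam = _draw_rts(len(design.test), config, rng)
            for j, t in enumerate(design.test):
                if config.learner == "guesser":
                    chosen = t.objects[int(rng.integers(4))]
                else:
                    chosen = choose_at_test(matrix, t, config, rng)
                rows.append(
                    _row(i, t, chosen, referent[t.probe_word], rt[j], bool(contam[j]))
                )
    else:
        raise SimulationError(f"unknown learner {config.learner!r}")
    return pd.DataFrame(rows, columns=RESPONSE_COLUMNS)


def _row(
    participant: int, t: TestTrial, chosen: str, target: str, rt: float, contam: bool
) -> dict:
    return {
        "participant_id": f"p{participant + 1:03d}",
        "trial_index": t.index,
        "set_label": t.set_label,
        "repetition": t.repetition,
        "probe_word": t.probe_word,
        "chosen_object": chosen,
        "correct": bool(chosen == target),
        "rt_ms": float(rt),
        "contaminated": contam,
    }


# ---------------------------------------------------------------------------
# synthetic lexicon

_COMMON_C = ["t", "d", "k", "m", "n", "s", "ɾ", "b", "p", "v"]
_COMMON_V = ["a", "e", "i", "o", "u"]


def synthetic_lexicon(
    n_words: int = 400,
    seed: int = 0,
    inventory: Optional[PhonemeInventory] = None,
) -> list[LexiconEntry]:
    """A synthetic CV-language frequency lexicon with Zipf-distributed token
    frequencies and a skewed segment distribution, standing in for a corpus
    biphone database (no published corpus is bundled)."""
    inv = inventory or bp_inventory()
    rng = np.random.default_rng(seed)
    cons, vows = list(inv.consonants), list(inv.vowels)
    cw = np.array([4.0 if c in _COMMON_C else 1.0 for c in cons])
    vw = np.array([4.0 if v in _COMMON_V else 1.0 for v in vows])
    cw, vw = cw / cw.sum(), vw / vw.sum()
    seen: dict[tuple[str, ...], None] = {}
    while len(seen) < n_words:
        n_syll = int(rng.choice([1, 2, 3], p=[0.2, 0.55, 0.25]))
        seq = []
        for _ in range(n_syll):
            seq.append(cons[int(rng.choice(len(cons), p=cw))])
            seq.append(vows[int(rng.choice(len(vows), p=vw))])
        seen.setdefault(tuple(seq), None)
    entries = []
    for rank, seq in enumerate(seen, start=1):
        freq = max(2, int(round(120000 / rank**1.05)))
        entries.append(
            LexiconEntry(orthography="".join(seq), phonemes=seq, token_frequency=freq)
        )
    return entries
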