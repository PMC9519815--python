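"""Cross-situational word-learning trial structure.

Training: 36 ambiguous 2x2 trials (two objects, then the two corresponding
words), 18 per stimulus set, never mixing sets within a trial.  Each of the 12
word-object pairs occurs six times; within a set each label is contrasted with
each of the other five labels (all 15 pairings once) plus one perfect matching
(3 pairings twice), the minimal schedule realizing both published counts.
Test: each pair probed twice in a 4AFC layout with three same-set foils, for
24 trials, preceded by two warm-up trials with familiar objects.

Timing per training trial: 950 ms silence, ~696 ms word, 700 ms pause,
~696 ms word, 950 ms pause (~4 s total); a 1 s central fixation separates
trials and is carried as metadata only.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .pseudowords import PP_MINUS, PP_PLUS

TRIAL_TIMING_MS = (950, 696, 700, 696, 950)
FIXATION_MS = 1000
WARMUP_OBJECTS = ("house", "duck", "ball", "cat")
CORNERS = ("UL", "UR", "LL", "LR")


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class WordObjectPair:
    pair_id: str
    word_id: str
    object_id: str
    set_label: str


@dataclass(frozen=True)
class TrainingTrial:
    index: int
    set_label: str
    left_object: str
    right_object: str
    first_word: str
    second_word: str
    timing_ms: tuple[int, ...] = TRIAL_TIMING_MS


@dataclass(frozen=True)
class TestTrial:
    index: int
    set_label: str
    objects: tuple[str, str, str, str]  # corner order UL, UR, LL, LR
    probe_word: str
    target_position: int  # 0..3 into CORNERS
    repetition: int  # 1 or 2 (0 for warm-up)


@dataclass(frozen=True)
class DesignSpec:
    pairs_per_set: int = 6
    exposures_per_pair: int = 6
    test_repetitions: int = 2
    interleave_policy: Literal["random_max_run", "alternate"] = "random_max_run"
    max_same_set_run: int = 2
    counterbalance_version: Literal["A", "B"] = "A"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.pairs_per_set * self.exposures_per_pair) % 2 != 0:
            raise DesignError("pairs_per_set * exposures_per_pair must be even")


@dataclass
class Design:
    pairs: list[WordObjectPair]
    training: list[TrainingTrial]
    test: list[TestTrial]
    warmup: list[TestTrial]
    spec: DesignSpec

    @property
    def referent_of(self) -> dict[str, str]:
        return {p.word_id: p.object_id for p in self.pairs}


def counterbalance_assignment(
    words: Sequence[tuple[str, str]],
    objects: Sequence[str],
    version: Literal["A", "B"] = "A",
    seed: int = 0,
) -> list[WordObjectPair]:
    """Randomly pair words with objects (version A); version B reuses A's
    draw but switches the object blocks across sets, so a word keeps its set
    while its object comes from the other set's block."""
    words = list(words)
    objects = list(objects)
    if len(words) != len(objects):
        raise DesignError("need as many objects as words")
    labels = [lab for _, lab in words]
    sets = sorted(set(labels))
    if len(sets) != 2:
        raise DesignError("expected exactly two stimulus sets")
    per_set = {s: [w for w, lab in words if lab == s] for s in sets}
    n0 = len(per_set[sets[0]])
    if n0 != len(per_set[sets[1]]):
        raise DesignError("sets must be the same size")
    rng = np.random.default_rng(seed)
    shuffled = list(objects)
    rng.shuffle(shuffled)
    blocks = {sets[0]: shuffled[:n0], sets[1]: shuffled[n0:]}
    if version == "B":
        blocks = {sets[0]: blocks[sets[1]], sets[1]: blocks[sets[0]]}
    elif version != "A":
        raise DesignError(f"unknown counterbalance version {version!r}")
    pairs = []
    for s in sets:
        for w, o in zip(per_set[s], blocks[s]):
            pairs.append(WordObjectPair(pair_id=w, word_id=w, object_id=o, set_label=s))
    return pairs


def build_pairing_schedule(
    pair_ids: Sequence[str], exposures: int, rng: np.random.Generator
) -> list[frozenset[str]]:
    """Schedule of unordered within-set pairings.

    With k labels: exposures = k-1 uses each of the C(k,2) pairings once;
    exposures = k (k even) additionally repeats one seeded perfect matching,
    so every label appears exactly ``exposures`` times.
    """
    k = len(pair_ids)
    if k < 2:
        raise DesignError("need at least two pairs per set")
    pairings = [frozenset(c) for c in itertools.combinations(pair_ids, 2)]
    if exposures == k - 1:
        return pairings
    if exposures == k and k % 2 == 0:
        order = list(pair_ids)
        rng.shuffle(order)
        matching = [frozenset(order[i : i + 2]) for i in range(0, k, 2)]
        return pairings + matching
    raise DesignError(
        f"no schedule for {k} labels with {exposures} exposures each"
    )


def _interleave_labels(
    counts: dict[str, int], policy: str, max_run: int, rng: np.random.Generator
) -> list[str]:
    labels = sorted(counts)
    if policy == "alternate":
        if len(set(counts.values())) != 1:
            raise DesignError("strict alternation needs equal counts")
        seq = []
        for i in range(sum(counts.values())):
            seq.append(labels[i % len(labels)])
        return seq
    if policy != "random_max_run":
        raise DesignError(f"unknown interleave policy {policy!r}")
    for _ in range(1000):  # constructive sampling with restart on dead ends
        remaining = dict(counts)
        seq: list[str] = []
        ok = True
        while any(remaining.values()):
            opts = [
                lab
                for lab in labels
                if remaining[lab] > 0
                and not (
                    len(seq) >= max_run
                    and all(s == lab for s in seq[-max_run:])
                )
            ]
            if not opts:
                ok = False
                break
            weights = np.array([remaining[lab] for lab in opts], dtype=float)
            lab = opts[rng.choice(len(opts), p=weights / weights.sum())]
            seq.append(lab)
            remaining[lab] -= 1
        if ok:
            return seq
    raise DesignError("could not interleave sets within the run-length constraint")


def assemble_training_trials(
    schedules: dict[str, list[frozenset[str]]],
    pairs: Sequence[WordObjectPair],
    spec: DesignSpec,
    rng: np.random.Generator,
) -> list[TrainingTrial]:
    """Interleave the per-set pairing schedules into the training sequence.

    Left/right object placement and word play-order are randomized such that
    the first-played word's referent sits on the left in half the trials
    (+/- 1), removing any side/order correspondence.
    """
    referent = {p.word_id: p.object_id for p in pairs}
    set_of = {p.word_id: p.set_label for p in pairs}
    for label, sched in schedules.items():
        for pairing in sched:
            for w in pairing:
                if set_of.get(w) != label:
                    raise DesignError(f"pair {w} is not in set {label}")
    counts = {label: len(s) for label, s in schedules.items()}
    order = _interleave_labels(counts, spec.interleave_policy, spec.max_same_set_run, rng)
    queues = {}
    for label, sched in schedules.items():
        q = list(sched)
        rng.shuffle(q)
        queues[label] = q
    n = len(order)
    first_on_left = np.zeros(n, dtype=bool)
    first_on_left[: n // 2 + n % 2] = True
    rng.shuffle(first_on_left)
    trials = []
    for i, label in enumerate(order):
        w1, w2 = sorted(queues[label].pop())
        if rng.random() < 0.5:
            w1, w2 = w2, w1  # w1 plays first
        if first_on_left[i]:
            left, right = referent[w1], referent[w2]
        else:
            left, right = referent[w2], referent[w1]
        trials.append(
            TrainingTrial(
                index=i,
                set_label=label,
                left_object=left,
                right_object=right,
                first_word=w1,
                second_word=w2,
            )
        )
    return trials


def build_test_trials(
    pairs: Sequence[WordObjectPair],
    spec: DesignSpec,
    rng: np.random.Generator,
) -> tuple[list[TestTrial], list[TestTrial]]:
    """4AFC test trials: each pair probed ``test_repetitions`` times among
    three same-set foils, foil appearances balanced within +/-1 per set and
    target corners balanced across the four positions; plus two warm-up
    trials with familiar objects."""
    by_set: dict[str, list[WordObjectPair]] = {}
    for p in pairs:
        by_set.setdefault(p.set_label, []).append(p)
    per_set_trials: dict[str, list[WordObjectPair]] = {}
    for label, ps in by_set.items():
        toks = ps * spec.test_repetitions
        rng.shuffle(toks)
        per_set_trials[label] = toks
    # merge the two sets' token streams in random order
    merged: list[WordObjectPair] = []
    streams = {lab: list(toks) for lab, toks in per_set_trials.items()}
    labels_seq = _interleave_labels(
        {lab: len(t) for lab, t in streams.items()}, "random_max_run", 10**9, rng
    )
    for lab in labels_seq:
        merged.append(streams[lab].pop(0))

    # balanced target corners per set
    corner_pool: dict[str, list[int]] = {}
    for label, toks in per_set_trials.items():
        m = len(toks)
        pool = [i % 4 for i in range(m)]
        rng.shuffle(pool)
        corner_pool[label] = pool

    for attempt in range(1000):
        foil_counts = {lab: {p.object_id: 0 for p in ps} for lab, ps in by_set.items()}
        draft: list[TestTrial] = []
        seen_rep: dict[str, int] = {}
        pools = {lab: list(v) for lab, v in corner_pool.items()}
        for i, pair in enumerate(merged):
            lab = pair.set_label
            others = [p.object_id for p in by_set[lab] if p.object_id != pair.object_id]
            counts = foil_counts[lab]
            rng.shuffle(others)
            others.sort(key=lambda o: counts[o])
            foils = others[:3]
            for o in foils:
                counts[o] += 1
            rep = seen_rep.get(pair.pair_id, 0) + 1
            seen_rep[pair.pair_id] = rep
            target_pos = pools[lab].pop()
            corner_objs: list[str] = [""] * 4
            corner_objs[target_pos] = pair.object_id
            slots = [j for j in range(4) if j != target_pos]
            rng.shuffle(foils)
            for j, o in zip(slots, foils):
                corner_objs[j] = o
            draft.append(
                TestTrial(
                    index=i,
                    set_label=lab,
                    objects=tuple(corner_objs),
                    probe_word=pair.word_id,
                    target_position=target_pos,
                    repetition=rep,
                )
            )
        spreads = [
            max(c.values()) - min(c.values()) for c in foil_counts.values() if c
        ]
        if all(s <= 1 for s in spreads):
            break
    else:
        raise DesignError("could not balance foil appearances within +/-1")

    warmups = []
    for j in range(2):
        objs = list(WARMUP_OBJECTS)
        rng.shuffle(objs)
        target = objs[int(rng.integers(4))]
        warmups.append(
            TestTrial(
                index=j,
                set_label="warmup",
                objects=tuple(objs),
                probe_word=target,
                target_position=objs.index(target),
                repetition=0,
            )
        )
    return draft, warmups


def generate_design(
    words: Sequence[tuple[str, str]],
    objects: Sequence[str],
    spec: DesignSpec,
) -> Design:
    """End-to-end design generation from 12 (word_id, set_label) and 12 object ids."""
    rng = np.random.default_rng(spec.seed)
    pairs = counterbalance_assignment(
        words, objects, version=spec.counterbalance_version, seed=spec.seed
    )
    schedules = {}
    for label in sorted({p.set_label for p in pairs}):
        ids = [p.pair_id for p in pairs if p.set_label == label]
        schedules[label] = build_pairing_schedule(ids, spec.exposures_per_pair, rng)
    training = assemble_training_trials(schedules, pairs, spec, rng)
    test, warmup = build_test_trials(pairs, spec, rng)
    return Design(pairs=pairs, training=training, test=test, warmup=warmup, spec=spec)


def default_words_objects(
    n_per_set: int = 6,
) -> tuple[list[tuple[str, str]], list[str]]:
    """Generic word/object ids for simulation-only designs."""
    words = [(f"wp{i+1:02d}", PP_PLUS) for i in range(n_per_set)]
    words += [(f"wm{i+1:02d}", PP_MINUS) for i in range(n_per_set)]
    objects = [f"obj{i+1:02d}" for i in range(2 * n_per_set)]
    return words, objects


# ---------------------------------------------------------------------------
# validation report

@dataclass
class DesignReport:
    n_training: int
    n_test: int
    trials_per_set: dict[str, int]
    cooccurrence: pd.DataFrame
    diagonal_min: int
    within_set_offdiag_max: int
    cross_set_max: int
    word_order_side_correlation: float
    foil_spread: dict[str, int]
    target_position_counts: dict[str, dict[int, int]]
    trial_duration_ms: int
    violations: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "cooccurrence"}
        payload["cooccurrence"] = self.cooccurrence.to_dict()
        text = json.dumps(payload, indent=2, default=str)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


def validate_design(design: Design) -> DesignReport:
    """Pure report: co-occurrence structure, balance statistics, violations."""
    pairs = design.pairs
    words = [p.word_id for p in pairs]
    objects = [p.object_id for p in pairs]
    set_of_word = {p.word_id: p.set_label for p in pairs}
    set_of_obj = {p.object_id: p.set_label for p in pairs}
    referent = design.referent_of
    co = pd.DataFrame(0, index=words, columns=objects, dtype=int)
    for t in design.training:
        for w in (t.first_word, t.second_word):
            for o in (t.left_object, t.right_object):
                co.loc[w, o] += 1
    diag = [co.loc[w, referent[w]] for w in words] if design.training else [0]
    within_off, cross = [0], [0]
    for w in words:
        for o in objects:
            if o == referent[w]:
                continue
            if set_of_word[w] == set_of_obj[o]:
                within_off.append(co.loc[w, o])
            else:
                cross.append(co.loc[w, o])
    # point-biserial: word played first (1/0) vs its referent on left (1/0)
    xs, ys = [], []
    for t in design.training:
        xs.append(1.0)
        ys.append(1.0 if referent[t.first_word] == t.left_object else 0.0)
        xs.append(0.0)
        ys.append(1.0 if referent[t.second_word] == t.left_object else 0.0)
    if design.training and np.std(xs) > 0 and np.std(ys) > 0:
        corr = float(np.corrcoef(xs, ys)[0, 1])
    else:
        corr = 0.0
    trials_per_set: dict[str, int] = {}
    for t in design.training:
        trials_per_set[t.set_label] = trials_per_set.get(t.set_label, 0) + 1
    foil_counts: dict[str, dict[str, int]] = {}
    pos_counts: dict[str, dict[int, int]] = {}
    violations: list[str] = []
    for t in design.test:
        tgt = referent[t.probe_word]
        if t.objects[t.target_position] != tgt:
            violations.append(f"test {t.index}: target not at target_position")
        if len(set(t.objects)) != 4:
            violations.append(f"test {t.index}: objects not distinct")
        if any(set_of_obj.get(o) != t.set_label for o in t.objects):
            violations.append(f"test {t.index}: mixed-set objects")
        for o in t.objects:
            if o != tgt:
                foil_counts.setdefault(t.set_label, {}).setdefault(o, 0)
                foil_counts[t.set_label][o] += 1
        pos_counts.setdefault(t.set_label, {}).setdefault(t.target_position, 0)
        pos_counts[t.set_label][t.target_position] += 1
    foil_spread = {
        lab: (max(c.values()) - min(c.values()) if c else 0)
        for lab, c in foil_counts.items()
    }
    for t in design.training:
        if set_of_obj[t.left_object] != t.set_label or set_of_obj[t.right_object] != t.set_label:
            violations.append(f"training {t.index}: mixed-set trial")
        if {t.first_word, t.second_word} != {
            k for k, v in referent.items() if v in (t.left_object, t.right_object)
        }:
            violations.append(f"training {t.index}: words do not label the objects")
    if design.training and min(diag) != design.spec.exposures_per_pair:
        violations.append("diagonal co-occurrence != exposures_per_pair")
    return DesignReport(
        n_training=len(design.training),
        n_test=len(design.test),
        trials_per_set=trials_per_set,
        cooccurrence=co,
        diagonal_min=int(min(diag)),
        within_set_offdiag_max=int(max(within_off)),
        cross_set_max=int(max(cross)),
        word_order_side_correlation=corr,
        foil_spread=foil_spread,
        target_position_counts=pos_counts,
        trial_duration_ms=int(sum(TRIAL_TIMING_MS)),
        violations=violations,
    )


# ---------------------------------------------------------------------------
# CSV I/O

def write_design(design: Design, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([asdict(p) for p in design.pairs]).to_csv(out / "pairs.csv", index=False)
    tr = pd.DataFrame([asdict(t) for t in design.training])
    if not tr.empty:
        tr["timing_ms"] = tr["timing_ms"].apply(lambda t: ";".join(map(str, t)))
    tr.to_csv(out / "training_trials.csv", index=False)
    te = pd.DataFrame([asdict(t) for t in design.test + design.warmup])
    if not te.empty:
        te["objects"] = te["objects"].apply(lambda t: ";".join(t))
    te.to_csv(out / "test_trials.csv", index=False)


def read_design(out_dir: str | Path, spec: Optional[DesignSpec] = None) -> Design:
    out = Path(out_dir)
    pairs = [
        WordObjectPair(**row)
        for row in pd.read_csv(out / "pairs.csv").to_dict("records")
    ]
    tr_rows = pd.read_csv(out / "training_trials.csv").to_dict("records")
    training = [
        TrainingTrial(
            index=int(r["index"]),
            set_label=r["set_label"],
            left_object=r["left_object"],
            right_object=r["right_object"],
            first_word=r["first_word"],
            second_word=r["second_word"],
            timing_ms=tuple(int(x) for x in str(r["timing_ms"]).split(";")),
        )
        for r in tr_rows
    ]
    te_rows = pd.read_csv(out / "test_trials.csv").to_dict("records")
    test, warmup = [], []
    for r in te_rows:
        t = TestTrial(
            index=int(r["index"]),
            set_label=r["set_label"],
            objects=tuple(str(r["objects"]).split(";")),
            probe_word=r["probe_word"],
            target_position=int(r["target_position"]),
            repetition=int(r["repetition"]),
        )
        (warmup if t.repetition == 0 else test).append(t)
    return Design(
        pairs=pairs, training=training, test=test, warmup=warmup,
        spec=spec or DesignSpec(),
    )
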