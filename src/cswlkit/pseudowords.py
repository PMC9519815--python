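"""Pseudoword search: build template-matching candidates by chaining biphones,
select a maximal-PP set, and recombine its syllables into a matched set with
slightly lower (but still high) phonotactic probability.

The search enumerates chains of biphones from the probability table: the
biphone at position p must end with the segment the biphone at p+1 starts
with, and each biphone must match the C/V classes the template demands at its
two positions.  Candidates equal to real lexicon words are excluded, so every
output is a novel form.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

from .lexicon import PhonemeInventory
from .phonotactics import (
    Aggregation,
    BiphoneProbTable,
    ScoredWord,
    score_word,
    set_mean_pp,
)

PP_PLUS = "PP_plus"
PP_MINUS = "PP_minus"


class PseudowordSearchError(ValueError):
    pass


@dataclass(frozen=True)
class WordTemplate:
    """C/V skeleton of the candidates; default is disyllabic CVCV."""

    pattern: tuple[str, ...] = ("C", "V", "C", "V")

    def __post_init__(self) -> None:
        if len(self.pattern) < 2:
            raise PseudowordSearchError("template must have length >= 2")
        if any(c not in ("C", "V") for c in self.pattern):
            raise PseudowordSearchError("template symbols must be 'C' or 'V'")

    def __len__(self) -> int:
        return len(self.pattern)


@dataclass(frozen=True)
class StimulusSet:
    """A labeled set of k scored pseudowords (6 in the published design)."""

    label: str
    words: tuple[ScoredWord, ...]
    mean_pp: float

    def __post_init__(self) -> None:
        forms = [w.phonemes for w in self.words]
        if len(set(forms)) != len(forms):
            raise PseudowordSearchError("stimulus-set words must be distinct")
        expected = set_mean_pp(self.words)
        if abs(expected - self.mean_pp) > 1e-12:
            raise PseudowordSearchError("mean_pp inconsistent with member PPs")

    @property
    def surfaces(self) -> tuple[str, ...]:
        return tuple(w.surface for w in self.words)


@dataclass(frozen=True)
class SelectionConstraints:
    """Greedy-checkable diversity constraints for set selection.

    max_shared_biphones: maximum number of (position, biphone) pairs any two
        chosen words may share (None disables).
    max_onset_reuse: maximum number of chosen words that may start with the
        same segment (None disables).
    """

    max_shared_biphones: Optional[int] = None
    max_onset_reuse: Optional[int] = None


def _class_of_biphone(biphone: tuple[str, str], inventory: PhonemeInventory) -> tuple[str, str]:
    return (
        "C" if inventory.class_of[biphone[0]] == "consonant" else "V",
        "C" if inventory.class_of[biphone[1]] == "consonant" else "V",
    )


def generate_candidates(
    table: BiphoneProbTable,
    template: WordTemplate,
    inventory: PhonemeInventory,
    lexicon_forms: Iterable[tuple[str, ...]] = (),
    aggregation: Aggregation = "sum",
) -> list[ScoredWord]:
    """Enumerate and score every chainable template-matching pseudoword.

    Returns candidates sorted by descending PP, ties broken by lexicographic
    phoneme order (so the ranking is deterministic).
    """
    known = frozenset(tuple(f) for f in lexicon_forms)
    length = len(template)
    # biphones usable at each 1-based position, filtered by template classes
    usable: dict[int, list[tuple[str, str]]] = {}
    for p in range(1, length):
        want = (template.pattern[p - 1], template.pattern[p])
        opts = [
            b
            for (pos, b) in table.prob
            if pos == p and _class_of_biphone(b, inventory) == want
        ]
        if not opts:
            raise PseudowordSearchError(
                f"no biphones in the table fit template position {p}"
            )
        usable[p] = sorted(opts)

    sequences: list[tuple[str, ...]] = []

    def extend(seq: tuple[str, ...], p: int) -> None:
        if p == length:
            sequences.append(seq)
            return
        for b in usable[p]:
            if b[0] == seq[-1]:
                extend(seq + (b[1],), p + 1)

    for b in usable[1]:
        extend(b, 2)

    novel = [s for s in sequences if s not in known]
    if not novel:
        raise PseudowordSearchError("no chainable novel candidates")
    scored = [score_word(s, table, aggregation) for s in novel]
    scored.sort(key=lambda w: (-w.pp, w.phonemes))
    return scored


def select_top_set(
    candidates: Sequence[ScoredWord],
    k: int = 6,
    constraints: SelectionConstraints = SelectionConstraints(),
    label: str = PP_PLUS,
) -> StimulusSet:
    """Greedy top-k selection down the ranking, skipping candidates that
    violate the diversity constraints against already-chosen words."""
    if len(candidates) < k:
        raise PseudowordSearchError(
            f"need at least {k} candidates, got {len(candidates)}"
        )
    chosen: list[ScoredWord] = []
    for cand in candidates:
        if _feasible(cand, chosen, constraints):
            chosen.append(cand)
            if len(chosen) == k:
                break
    if len(chosen) < k:
        raise PseudowordSearchError(
            f"only {len(chosen)} candidates satisfy the constraints (need {k})"
        )
    return StimulusSet(label=label, words=tuple(chosen), mean_pp=set_mean_pp(chosen))


def _shared_biphones(a: ScoredWord, b: ScoredWord) -> int:
    pa = {(p, bp) for p, bp, _ in a.biphone_probs}
    pb = {(p, bp) for p, bp, _ in b.biphone_probs}
    return len(pa & pb)


def _feasible(
    cand: ScoredWord, chosen: Sequence[ScoredWord], constraints: SelectionConstraints
) -> bool:
    if any(cand.phonemes == w.phonemes for w in chosen):
        return False
    if constraints.max_shared_biphones is not None:
        if any(
            _shared_biphones(cand, w) > constraints.max_shared_biphones for w in chosen
        ):
            return False
    if constraints.max_onset_reuse is not None:
        same_onset = sum(1 for w in chosen if w.phonemes[0] == cand.phonemes[0])
        if same_onset >= constraints.max_onset_reuse:
            return False
    return True


def _syllables(word: ScoredWord) -> list[tuple[str, ...]]:
    # CV template assumed: split into consecutive CV units
    seq = word.phonemes
    if len(seq) % 2 != 0:
        raise PseudowordSearchError("syllable recombination requires an even template")
    return [tuple(seq[i : i + 2]) for i in range(0, len(seq), 2)]


def recombine_biphones(
    pp_plus: StimulusSet,
    table: BiphoneProbTable,
    template: WordTemplate = WordTemplate(),
    lexicon_forms: Iterable[tuple[str, ...]] = (),
    *,
    floor: float = 0.75,
    mode: Literal["syllable", "biphone"] = "syllable",
    aggregation: Aggregation = "sum",
    k: Optional[int] = None,
) -> StimulusSet:
    """Recombine the PP+ set's material into a novel PP- set.

    In the default ``syllable`` mode, the CV syllables of the PP+ words are
    rearranged into new orders and positions (a word-final syllable may
    reappear word-initially).  In ``biphone`` mode the candidate space is any
    chainable arrangement of the PP+ words' positional biphones.  The result
    is the k highest-PP novel recombinations whose mean is strictly below the
    PP+ mean and at or above ``floor`` times it.
    """
    k = k if k is not None else len(pp_plus.words)
    known = frozenset(tuple(f) for f in lexicon_forms)
    excluded = known | {w.phonemes for w in pp_plus.words}

    if mode == "syllable":
        syls = []
        for w in pp_plus.words:
            for s in _syllables(w):
                if s not in syls:
                    syls.append(s)
        n_slots = len(template) // 2
        forms = {
            sum(combo, ()): None
            for combo in itertools.permutations(syls, n_slots)
        }
        candidates = [
            score_word(f, table, aggregation) for f in forms if f not in excluded
        ]
    elif mode == "biphone":
        allowed = {(p, bp) for w in pp_plus.words for p, bp, _ in w.biphone_probs}
        sub = BiphoneProbTable(
            prob={key: table.prob.get(key, 0.0) for key in allowed},
            numer={key: table.numer.get(key, 0.0) for key in allowed},
            denom=dict(table.denom),
            source_size=table.source_size,
        )
        inv = _inventory_from_biphones(allowed)
        candidates = [
            score_word(w.phonemes, table, aggregation)
            for w in generate_candidates(sub, template, inv, excluded, aggregation)
        ]
    else:
        raise PseudowordSearchError(f"unknown recombination mode {mode!r}")

    candidates = [c for c in candidates if c.phonemes not in excluded]
    candidates.sort(key=lambda w: (-w.pp, w.phonemes))
    if len(candidates) < k:
        raise PseudowordSearchError("recombination space exhausted before k words")

    chosen = candidates[:k]
    next_idx = k
    target = pp_plus.mean_pp
    while set_mean_pp(chosen) >= target:
        if next_idx >= len(candidates):
            raise PseudowordSearchError(
                "cannot recombine below the PP+ mean (candidates exhausted)"
            )
        # replace the current lowest-PP member with the next candidate down
        lowest = min(range(k), key=lambda i: chosen[i].pp)
        replacement = candidates[next_idx]
        next_idx += 1
        if replacement.pp >= chosen[lowest].pp:
            continue
        chosen[lowest] = replacement
    mean = set_mean_pp(chosen)
    if mean < floor * target:
        raise PseudowordSearchError(
            f"recombined mean {mean:.4g} fell below floor {floor:.2f} x PP+ mean"
        )
    chosen.sort(key=lambda w: (-w.pp, w.phonemes))
    return StimulusSet(label=PP_MINUS, words=tuple(chosen), mean_pp=mean)


def _inventory_from_biphones(allowed: set[tuple[int, tuple[str, str]]]) -> PhonemeInventory:
    # Minimal inventory for biphone-mode chaining; classes inferred from the
    # default BP inventory where possible, defaulting alternating C/V.
    from .lexicon import bp_inventory

    base = bp_inventory()
    symbols: list[str] = []
    class_of: dict[str, str] = {}
    for _, (a, b) in allowed:
        for s in (a, b):
            if s not in class_of:
                symbols.append(s)
                class_of[s] = base.class_of.get(s, "consonant")
    return PhonemeInventory(symbols=tuple(symbols), class_of=class_of)


def write_stimulus_sets(sets: Iterable[StimulusSet], path: str | Path) -> None:
    """TSV serialization: label, word id, space-joined phonemes, pp."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("label\tword_id\tphonemes\tpp\n")
        for sset in sets:
            for i, w in enumerate(sset.words, start=1):
                fh.write(f"{sset.label}\t{sset.label}_{i:02d}\t{' '.join(w.phonemes)}\t{w.pp:.12g}\n")


def read_stimulus_sets(path: str | Path) -> dict[str, list[tuple[str, tuple[str, ...], float]]]:
    """Read the TSV back as {label: [(word_id, phonemes, pp), ...]}."""
    out: dict[str, list[tuple[str, tuple[str, ...], float]]] = {}
    with Path(path).open(encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("label"):
            raise PseudowordSearchError("missing stimulus set header")
        for line in fh:
            label, word_id, phon, pp = line.rstrip("\n").split("\t")
            out.setdefault(label, []).append((word_id, tuple(phon.split()), float(pp)))
    return out
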