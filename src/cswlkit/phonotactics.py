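"""Positional biphone phonotactic probabilities.

The probability of biphone *b* at position *p* (1-based index of the
biphone's first segment) is the log10 token frequency of the words carrying
*b* at *p*, divided by the total log10 token frequency of all words that have
any biphone at *p* (i.e. words of length >= p+1):

    prob(p, b) = sum_{w: w[p..p+1] = b} log10 freq(w)
                 / sum_{w: len(w) >= p+1} log10 freq(w)

Log-weighting means the statistic is a token measure but frequency-1 words
contribute zero weight (log10 1 = 0); no smoothing is applied.  For each
position the probabilities sum to one whenever the denominator is positive.

Word-level phonotactic probability (PP) is the sum of the word's positional
biphone probabilities by default (the Vitevitch-Luce convention); a mean
aggregation is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .lexicon import LexiconEntry

Biphone = tuple[str, str]
Aggregation = Literal["sum", "mean"]


class PhonotacticsError(ValueError):
    pass


@dataclass(frozen=True)
class BiphoneProbTable:
    """Positional biphone probabilities with their numerators and denominators.

    ``numer[(p, b)]`` is the summed log10 frequency of words with biphone ``b``
    at position ``p``; ``denom[p]`` the summed log10 frequency of words with
    any biphone at ``p``.  Denominators are exposed so that exact recomputation
    (e.g. after rescaling frequencies) can be asserted.
    """

    prob: dict[tuple[int, Biphone], float]
    numer: dict[tuple[int, Biphone], float]
    denom: dict[int, float]
    source_size: int

    def positions(self) -> tuple[int, ...]:
        return tuple(sorted(self.denom))

    def biphones_at(self, position: int) -> list[Biphone]:
        return [b for (p, b) in self.prob if p == position]

    def get(self, position: int, biphone: Biphone) -> float:
        return self.prob.get((position, biphone), 0.0)


def compute_biphone_table(lexicon: Sequence[LexiconEntry]) -> BiphoneProbTable:
    """Build the positional biphone probability table from a frequency lexicon."""
    if not lexicon:
        raise PhonotacticsError("empty lexicon")
    numer: dict[tuple[int, Biphone], float] = {}
    denom: dict[int, float] = {}
    for entry in lexicon:
        logf = math.log10(entry.token_frequency)
        seq = entry.phonemes
        for p in range(1, len(seq)):  # biphone starting at 1-based position p
            biphone = (seq[p - 1], seq[p])
            numer[(p, biphone)] = numer.get((p, biphone), 0.0) + logf
            denom[p] = denom.get(p, 0.0) + logf
    if not denom:
        raise PhonotacticsError("no word in the lexicon has two or more phonemes")
    prob = {
        (p, b): (numer[(p, b)] / denom[p]) if denom[p] > 0 else 0.0
        for (p, b) in numer
        if denom[p] > 0
    }
    return BiphoneProbTable(prob=prob, numer=numer, denom=denom, source_size=len(lexicon))


@dataclass(frozen=True)
class ScoredWord:
    """A phoneme sequence with its positional biphone probabilities and PP."""

    phonemes: tuple[str, ...]
    biphone_probs: tuple[tuple[int, Biphone, float], ...]
    pp: float
    aggregation: Aggregation
    n_unseen: int

    @property
    def all_unseen(self) -> bool:
        return self.n_unseen == len(self.biphone_probs)

    @property
    def surface(self) -> str:
        return "".join(self.phonemes)


def score_word(
    phonemes: Sequence[str],
    table: BiphoneProbTable,
    aggregation: Aggregation = "sum",
) -> ScoredWord:
    """Score a word against a biphone table.

    Biphones absent from the table contribute probability 0 and are counted in
    ``n_unseen``.
    """
    phonemes = tuple(phonemes)
    if len(phonemes) < 2:
        raise PhonotacticsError("a word needs at least 2 phonemes to score")
    if aggregation not in ("sum", "mean"):
        raise PhonotacticsError(f"unknown aggregation {aggregation!r}")
    probs: list[tuple[int, Biphone, float]] = []
    n_unseen = 0
    for p in range(1, len(phonemes)):
        b = (phonemes[p - 1], phonemes[p])
        pr = table.get(p, b)
        if (p, b) not in table.prob:
            n_unseen += 1
        probs.append((p, b, pr))
    values = [pr for _, _, pr in probs]
    pp = sum(values) if aggregation == "sum" else sum(values) / len(values)
    return ScoredWord(
        phonemes=phonemes,
        biphone_probs=tuple(probs),
        pp=pp,
        aggregation=aggregation,
        n_unseen=n_unseen,
    )


def set_mean_pp(words: Iterable[ScoredWord | float]) -> float:
    """Arithmetic mean PP of a stimulus set (accepts ScoredWords or raw values)."""
    values = [w.pp if isinstance(w, ScoredWord) else float(w) for w in words]
    if not values:
        raise PhonotacticsError("empty stimulus set")
    return sum(values) / len(values)


def write_table(table: BiphoneProbTable, path: str | Path) -> None:
    """Serialize as TSV: position, phoneme1, phoneme2, probability, numerator, denominator."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("position\tphoneme1\tphoneme2\tprobability\tnumerator\tdenominator\n")
        for (p, (a, b)) in sorted(table.prob):
            fh.write(
                f"{p}\t{a}\t{b}\t{table.prob[(p, (a, b))]:.12g}\t"
                f"{table.numer[(p, (a, b))]:.12g}\t{table.denom[p]:.12g}\n"
            )


def read_table(path: str | Path) -> BiphoneProbTable:
    prob: dict[tuple[int, Biphone], float] = {}
    numer: dict[tuple[int, Biphone], float] = {}
    denom: dict[int, float] = {}
    with Path(path).open(encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("position"):
            raise PhonotacticsError("missing biphone table header")
        for line in fh:
            p_s, a, b, pr, nu, de = line.rstrip("\n").split("\t")
            p = int(p_s)
            prob[(p, (a, b))] = float(pr)
            numer[(p, (a, b))] = float(nu)
            denom[p] = float(de)
    return BiphoneProbTable(prob=prob, numer=numer, denom=denom, source_size=-1)
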