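"""Phonemic frequency lexicons: inventories, tokenization, and TSV I/O.

A lexicon row is ``orthography<TAB>phonemes<TAB>frequency`` with the phoneme
field space-delimited, so multi-character IPA symbols (affricates such as
"d͡ʒ") are unambiguous single tokens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

CONSONANT = "consonant"
VOWEL = "vowel"


class LexiconError(ValueError):
    """Malformed lexicon or inventory input."""


class TokenizationError(LexiconError):
    """A phoneme string contains a symbol outside the inventory."""


@dataclass(frozen=True)
class PhonemeInventory:
    """The segment alphabet: phoneme symbols and their C/V class.

    Symbols may be multi-character; tokenization is whitespace-based, so no
    prefix ambiguity can arise.
    """

    symbols: tuple[str, ...]
    class_of: dict[str, str] = field(hash=False)

    def __post_init__(self) -> None:
        if not self.symbols:
            raise LexiconError("inventory must contain at least one symbol")
        if len(set(self.symbols)) != len(self.symbols):
            raise LexiconError("inventory symbols must be unique")
        for s in self.symbols:
            if self.class_of.get(s) not in (CONSONANT, VOWEL):
                raise LexiconError(f"symbol {s!r} lacks a consonant/vowel class")

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.class_of

    @property
    def consonants(self) -> tuple[str, ...]:
        return tuple(s for s in self.symbols if self.class_of[s] == CONSONANT)

    @property
    def vowels(self) -> tuple[str, ...]:
        return tuple(s for s in self.symbols if self.class_of[s] == VOWEL)


@dataclass(frozen=True)
class LexiconEntry:
    """One word: orthography, phoneme token sequence, corpus token frequency."""

    orthography: str
    phonemes: tuple[str, ...]
    token_frequency: int

    def __post_init__(self) -> None:
        if len(self.phonemes) < 1:
            raise LexiconError("entry must have at least one phoneme")
        if not isinstance(self.token_frequency, int) or self.token_frequency < 1:
            raise LexiconError(
                f"token_frequency must be an integer >= 1, got {self.token_frequency!r}"
            )


def bp_inventory() -> PhonemeInventory:
    """A Brazilian-Portuguese-style phoneme inventory (oral vowels, common
    consonants, and the [t͡ʃ]/[d͡ʒ] affricates that arise from palatalization)."""
    consonants = [
        "p", "b", "t", "d", "k", "g", "f", "v", "s", "z",
        "ʃ", "ʒ", "m", "n", "ɲ", "l", "ʎ", "ɾ", "ʁ", "t͡ʃ", "d͡ʒ",
    ]
    vowels = ["a", "e", "i", "o", "u", "ɛ", "ɔ"]
    class_of = {c: CONSONANT for c in consonants}
    class_of.update({v: VOWEL for v in vowels})
    return PhonemeInventory(symbols=tuple(consonants + vowels), class_of=class_of)


def tokenize_phonemes(raw: str, inventory: PhonemeInventory) -> tuple[str, ...]:
    """Split a space-delimited phoneme string and check every token.

    Raises :class:`TokenizationError` naming the offending symbol and its
    1-based position; an empty string is an error (a word has >= 1 segment).
    """
    tokens = raw.split()
    if not tokens:
        raise TokenizationError("empty phoneme string")
    for i, tok in enumerate(tokens, start=1):
        if tok not in inventory:
            raise TokenizationError(
                f"unknown phoneme {tok!r} at position {i} in {raw!r}"
            )
    return tuple(tokens)


@dataclass(frozen=True)
class RowError:
    line_number: int
    message: str


def read_lexicon(
    path: str | Path,
    inventory: PhonemeInventory,
    *,
    delimiter: str = "\t",
    strict: bool = False,
) -> tuple[list[LexiconEntry], list[RowError]]:
    """Read a lexicon TSV (orthography, phonemes, frequency).

    Invalid rows are skipped with a logged warning and reported in the second
    return value; with ``strict=True`` the first invalid row raises.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    entries: list[LexiconEntry] = []
    rejected: list[RowError] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            try:
                entries.append(_parse_row(line, inventory, delimiter))
            except LexiconError as exc:
                if strict:
                    raise LexiconError(f"line {lineno}: {exc}") from exc
                logger.warning("skipping lexicon line %d: %s", lineno, exc)
                rejected.append(RowError(lineno, str(exc)))
    return entries, rejected


def _parse_row(line: str, inventory: PhonemeInventory, delimiter: str) -> LexiconEntry:
    parts = line.split(delimiter)
    if len(parts) != 3:
        raise LexiconError(f"expected 3 fields, got {len(parts)}")
    orth, phon_raw, freq_raw = (p.strip() for p in parts)
    try:
        freq = int(freq_raw)
    except ValueError:
        raise LexiconError(f"non-integer frequency {freq_raw!r}") from None
    if freq < 1:
        raise LexiconError(f"frequency must be >= 1, got {freq}")
    phonemes = tokenize_phonemes(phon_raw, inventory)
    return LexiconEntry(orthography=orth, phonemes=phonemes, token_frequency=freq)


def write_lexicon(
    entries: Iterable[LexiconEntry], path: str | Path, *, delimiter: str = "\t"
) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for e in entries:
            fh.write(f"{e.orthography}{delimiter}{' '.join(e.phonemes)}{delimiter}{e.token_frequency}\n")


def read_inventory(path: str | Path) -> PhonemeInventory:
    """Read an inventory TSV with columns (symbol, class in {consonant, vowel})."""
    path = Path(path)
    symbols: list[str] = []
    class_of: dict[str, str] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise LexiconError(f"inventory line {lineno}: expected 2 fields")
            sym, cls = parts[0].strip(), parts[1].strip()
            if cls not in (CONSONANT, VOWEL):
                raise LexiconError(f"inventory line {lineno}: bad class {cls!r}")
            symbols.append(sym)
            class_of[sym] = cls
    return PhonemeInventory(symbols=tuple(symbols), class_of=class_of)


def write_inventory(inventory: PhonemeInventory, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for s in inventory.symbols:
            fh.write(f"{s}\t{inventory.class_of[s]}\n")


def lexicon_forms(entries: Sequence[LexiconEntry]) -> frozenset[tuple[str, ...]]:
    """The set of phoneme sequences in the lexicon (for novelty checks)."""
    return frozenset(e.phonemes for e in entries)
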