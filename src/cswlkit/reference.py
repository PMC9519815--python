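"""The published 12-pseudoword stimulus list with per-word phonotactic
probabilities (PP), as printed: six high-PP (PP+) items and six recombined,
slightly lower-PP (PP-) items built from the same syllables.  Used as a fixed
input for set-level summaries and as the canonical word ids of the design."""

from __future__ import annotations

PP_PLUS_WORDS: dict[str, float] = {
    "d͡ʒ i n i": 0.0090,
    "d e t a": 0.0085,
    "p e m i": 0.0082,
    "s u t e": 0.0084,
    "v i k o": 0.0080,
    "b a ɾ a": 0.0090,
}

PP_MINUS_WORDS: dict[str, float] = {
    "n i p e": 0.0066,
    "t a d͡ʒ i": 0.0074,
    "m i d e": 0.0075,
    "t e b a": 0.0074,
    "k o s u": 0.0078,
    "ɾ a v i": 0.0073,
}


def words(set_label: str) -> list[tuple[tuple[str, ...], float]]:
    table = {"PP_plus": PP_PLUS_WORDS, "PP_minus": PP_MINUS_WORDS}[set_label]
    return [(tuple(k.split()), v) for k, v in table.items()]
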