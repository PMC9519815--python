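"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive each quantity with naive nested loops and must
stay independent of the cswlkit code paths they check.
"""

import itertools
import math


def brute_force_biphone_table(entries):
    """Positional biphone probabilities by direct enumeration over words."""
    max_len = max(len(e.phonemes) for e in entries)
    prob = {}
    for p in range(1, max_len):
        words_at_p = [e for e in entries if len(e.phonemes) >= p + 1]
        denom = sum(math.log10(e.token_frequency) for e in words_at_p)
        if denom <= 0:
            continue
        biphones = {(e.phonemes[p - 1], e.phonemes[p]) for e in words_at_p}
        for b in biphones:
            num = sum(
                math.log10(e.token_frequency)
                for e in words_at_p
                if (e.phonemes[p - 1], e.phonemes[p]) == b
            )
            prob[(p, b)] = num / denom
    return prob


def brute_force_score(phonemes, prob, aggregation="sum"):
    vals = [
        prob.get((p, (phonemes[p - 1], phonemes[p])), 0.0)
        for p in range(1, len(phonemes))
    ]
    return sum(vals) if aggregation == "sum" else sum(vals) / len(vals)


def best_feasible_set(candidates, k, max_shared_biphones):
    """Exhaustive search over all k-subsets for the maximum-total-PP feasible
    set (ties broken toward earlier ranks)."""

    def biphones(word):
        return {(p, b) for p, b, _ in word.biphone_probs}

    def feasible(subset):
        for a, b in itertools.combinations(subset, 2):
            if len(biphones(a) & biphones(b)) > max_shared_biphones:
                return False
        return True

    best, best_pp = None, -1.0
    for combo in itertools.combinations(range(len(candidates)), k):
        subset = [candidates[i] for i in combo]
        if feasible(subset):
            total = sum(w.pp for w in subset)
            if total > best_pp + 1e-12:
                best, best_pp = combo, total
    if best is None:
        return None
    return [candidates[i] for i in best]
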