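import numpy as np
import pytest

from cswlkit.lexicon import LexiconEntry, bp_inventory
from cswlkit.calibration import make_study_design
from cswlkit.simulate import synthetic_lexicon


@pytest.fixture(scope="session")
def inventory():
    return bp_inventory()


@pytest.fixture(scope="session")
def tiny_lexicon():
    """Hand-checkable lexicon: two words sharing the initial biphone."""
    return [
        LexiconEntry("bata", ("b", "a", "t", "a"), 100),
        LexiconEntry("babo", ("b", "a", "b", "o"), 10),
    ]


@pytest.fixture(scope="session")
def toy_lexicon(inventory):
    return synthetic_lexicon(n_words=120, seed=42, inventory=inventory)


@pytest.fixture(scope="session")
def study_design():
    return make_study_design(seed=0)


@pytest.fixture(scope="session")
def random_small_lexicons(inventory):
    """A suite of seeded random lexicons (<= 20 words) for oracle checks."""
    rng = np.random.default_rng(2024)
    cons, vows = inventory.consonants[:6], inventory.vowels[:4]
    suites = []
    for _ in range(25):
        n = int(rng.integers(1, 21))
        entries, seen = [], set()
        while len(entries) < n:
            length = int(rng.integers(2, 7))
            seq = tuple(
                (cons if i % 2 == 0 else vows)[int(rng.integers(0, 4))]
                for i in range(length)
            )
            if seq in seen:
                continue
            seen.add(seq)
            entries.append(
                LexiconEntry("".join(seq), seq, int(rng.integers(1, 5000)))
            )
        suites.append(entries)
    return suites
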