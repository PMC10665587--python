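import random
import re

import pytest

from cryptogc import GC_MOTIF, parse_pattern, table1_centers_path
from cryptogc.pattern import AMBIGUOUS_AA, ANY, CANONICAL_AA, CLASS, NOT_CLASS


@pytest.fixture(scope="session")
def gc_pattern():
    return parse_pattern(GC_MOTIF)


@pytest.fixture(scope="session")
def table1_fasta():
    return str(table1_centers_path())


# ---- shared oracle helpers -------------------------------------------------

ALL_LETTERS = CANONICAL_AA + AMBIGUOUS_AA


def pattern_to_regex(pattern) -> str:
    """Mechanical element-by-element translation to a character-class regex.

    Independent of the scanner: classes become literal character classes,
    negated classes the complement within the canonical alphabet, and
    wildcards greedy repeats over every accepted letter (ambiguity codes
    included, since only wildcards accept them).
    """
    parts = []
    for el in pattern.elements:
        if el.kind == ANY:
            body = f"[{ALL_LETTERS}]"
        elif el.kind == CLASS:
            body = "[" + "".join(sorted(el.residues)) + "]"
        else:
            allowed = sorted(set(CANONICAL_AA) - el.residues)
            body = "[" + "".join(allowed) + "]"
        if el.min_repeat == el.max_repeat == 1:
            parts.append(body)
        elif el.min_repeat == el.max_repeat:
            parts.append(body + f"{{{el.min_repeat}}}")
        else:
            parts.append(body + f"{{{el.min_repeat},{el.max_repeat}}}")
    return "".join(parts)


def regex_scan(pattern, sequence: str):
    """Overlapping regex search anchored at every start; (start0, end0) spans."""
    rx = re.compile(pattern_to_regex(pattern))
    seq = sequence.upper()
    spans = []
    for s in range(len(seq)):
        m = rx.match(seq, s)
        if m:
            spans.append((s, m.end()))
    return spans


def random_pattern(rng: random.Random, allow_variable: bool = True):
    """A random small PROSITE-dialect pattern (returns its source text)."""
    n_el = rng.randint(1, 6)
    tokens = []
    for _ in range(n_el):
        kind = rng.choice(["class", "not", "any", "letter"])
        if kind == "class":
            k = rng.randint(1, 4)
            tokens.append("[" + "".join(rng.sample(CANONICAL_AA, k)) + "]")
        elif kind == "not":
            k = rng.randint(1, 3)
            tokens.append("{" + "".join(rng.sample(CANONICAL_AA, k)) + "}")
        elif kind == "letter":
            tokens.append(rng.choice(CANONICAL_AA))
        else:
            if allow_variable and rng.random() < 0.4:
                lo = rng.randint(1, 3)
                hi = lo + rng.randint(0, 3)
                tokens.append(f"x({lo},{hi})")
            elif rng.random() < 0.5:
                tokens.append(f"x({rng.randint(1, 4)})")
            else:
                tokens.append("x")
    return "-".join(tokens)


def random_sequence(rng: random.Random, length: int, with_ambiguity: bool = False):
    alphabet = ALL_LETTERS if with_ambiguity else CANONICAL_AA
    return "".join(rng.choice(alphabet) for _ in range(length))
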