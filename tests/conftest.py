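"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from mirscout.folding import _DEFAULT_WEIGHTS


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_rna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=n))


# ---------------------------------------------------------------------------
# independent oracles (deliberately brute-force, never sharing code with the
# implementations they check)
# ---------------------------------------------------------------------------

def enumerate_nested_structures(seq: str, min_loop: int = 3):
    """Yield every nested pair set with hairpin loops >= min_loop (canonical
    pairs only), by explicit recursion over intervals."""

    def rec(i: int, j: int):
        if j - i < min_loop + 1:
            yield frozenset()
            return
        # position i unpaired
        for rest in rec(i + 1, j):
            yield rest
        # position i paired with some k
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) in _DEFAULT_WEIGHTS:
                for left in rec(i + 1, k - 1):
                    for right in rec(k + 1, j):
                        yield frozenset({(i, k)}) | left | right

    yield from rec(0, len(seq) - 1)


def enumerated_min_energy(seq: str, min_loop: int = 3) -> float:
    """Optimal energy by exhaustive enumeration (tractable for len <= ~14)."""
    best = 0.0
    for pairs in enumerate_nested_structures(seq, min_loop):
        e = sum(_DEFAULT_WEIGHTS[(seq[i], seq[j])] for i, j in pairs)
        if e < best:
            best = e
    return best


def hamming_all_windows(query: str, transcript: str, max_mm: int):
    """All (start, mismatches) by direct enumeration; N never matches."""
    out = []
    L = len(query)
    for s in range(len(transcript) - L + 1):
        win = transcript[s : s + L]
        mm = sum(1 for a, b in zip(win, query) if a != b or a == "N" or b == "N")
        if mm <= max_mm:
            out.append((s, mm))
    return out
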