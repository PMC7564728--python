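"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from tlpkit import (
    THAUMATIN_SIGNATURE, PrositePattern, make_genome, parse_prosite,
)


@pytest.fixture(scope="session")
def signature() -> PrositePattern:
    return parse_prosite(THAUMATIN_SIGNATURE)


@pytest.fixture(scope="session")
def small_genome():
    """Compact default-condition genome bundle (19 true loci / 32
    transcripts / 13 decoys) shared across tests."""
    return make_genome(seed=7, dense_chromosomes=True)


def brute_force_scan(sequence: str, pattern: PrositePattern,
                     all_expansions: bool = False):
    """Enumerate every start and every repeat-count combination.

    Independent of the production matcher: tries each combination by
    direct residue-by-residue comparison.  Returns (start, end) pairs,
    1-based inclusive; for a fixed start only the first valid combination
    in shortest-first (lexicographic repeat-vector) order unless
    ``all_expansions``.
    """
    results = []
    ranges = [range(e.min_repeat, e.max_repeat + 1) for e in pattern.elements]
    for start in range(len(sequence)):
        for combo in itertools.product(*ranges):
            pos = start
            ok = True
            for elem, rep in zip(pattern.elements, combo):
                for _ in range(rep):
                    if pos >= len(sequence) or not elem.matches(sequence[pos]):
                        ok = False
                        break
                    pos += 1
                if not ok:
                    break
            if ok:
                results.append((start + 1, pos))
                if not all_expansions:
                    break
    return results


def random_pattern(rng: np.random.Generator) -> PrositePattern:
    """A random small PROSITE-style pattern over a reduced alphabet."""
    alphabet = "ACDG"
    n = int(rng.integers(2, 6))
    tokens = []
    for _ in range(n):
        kind = rng.integers(0, 3)
        if kind == 0:
            tok = str(rng.choice(list(alphabet)))
        elif kind == 1:
            tok = "x"
        else:
            size = int(rng.integers(2, 4))
            tok = "[" + "".join(
                rng.choice(list(alphabet), size=size, replace=False)) + "]"
        if rng.random() < 0.4:
            lo = int(rng.integers(1, 3))
            hi = lo + int(rng.integers(0, 3))
            tok += f"({lo},{hi})" if hi > lo else f"({lo})"
        tokens.append(tok)
    return parse_prosite("-".join(tokens))
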