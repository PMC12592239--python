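"""Shared fixtures and independent oracles.

The oracles here (window-by-window IUPAC matching, naive Hamming scan)
are deliberately written from scratch, without reusing the package's
matching machinery, so tests compare two independent routes.
"""

from __future__ import annotations

import numpy as np
import pytest

from sthguide.synthetic import generate_synthetic_genome

# Independent IUPAC table (do not import the package's).
ORACLE_IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}
_ORACLE_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def oracle_revcomp(s: str) -> str:
    return s.translate(_ORACLE_COMP)[::-1]


def oracle_window_match(pattern: str, window: str) -> bool:
    return len(pattern) == len(window) and all(
        w in ORACLE_IUPAC[p] for p, w in zip(pattern, window)
    )


def brute_pam_sites(seq: str, patterns: list[str]) -> set[tuple[int, str]]:
    """Every (start, strand) whose strand-oriented window matches a pattern."""
    hits = set()
    for pat in patterns:
        k = len(pat)
        rc = oracle_revcomp(pat)
        for i in range(len(seq) - k + 1):
            w = seq[i:i + k]
            if oracle_window_match(pat, w):
                hits.add((i, "+"))
            if oracle_window_match(rc, w):
                hits.add((i, "-"))
    return hits


def brute_hamming(seq: str, query: str, max_mm: int) -> dict[tuple[int, str], int]:
    """(start, strand) -> mismatch count for every window within max_mm."""
    out = {}
    k = len(query)
    rc = oracle_revcomp(query)
    palindrome = rc == query
    for i in range(len(seq) - k + 1):
        w = seq[i:i + k]
        d = sum(a != b for a, b in zip(w, query))
        if d <= max_mm:
            out[(i, "+")] = d
        if not palindrome:
            d = sum(a != b for a, b in zip(w, rc))
            if d <= max_mm:
                out[(i, "-")] = d
    return out


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


@pytest.fixture(scope="session")
def fixture_genome():
    """The standard planted-truth genome (seed 1)."""
    return generate_synthetic_genome(seed=1)
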