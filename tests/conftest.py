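"""Shared fixtures and independent oracles used across the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from ringsurvey.io import ProteinRecord
from ringsurvey.motif import OctetGrammar


def brute_force_octets(sequence: str, grammar: OctetGrammar) -> set[tuple[int, ...]]:
    """Naive backtracking enumerator of all grammar-compatible octets.

    Independent of the scanner: walks every residue position at every
    ligand slot, checking residue membership and spacer bounds directly.
    Returns the set of 1-based ligand-position tuples.
    """
    n = len(sequence)
    found: set[tuple[int, ...]] = set()

    def recurse(prefix: list[int]) -> None:
        slot = len(prefix)
        if slot == 8:
            found.add(tuple(prefix))
            return
        start = prefix[-1] + 1 if prefix else 1
        for pos in range(start, n + 1):
            if prefix:
                spacer = pos - prefix[-1] - 1
                lo, hi = grammar.spacers[slot - 1]
                if spacer > hi:
                    break
                if spacer < lo:
                    continue
            if sequence[pos - 1] not in grammar.residues[slot]:
                continue
            prefix.append(pos)
            recurse(prefix)
            prefix.pop()

    recurse([])
    return found


def random_achg_sequence(rng: np.random.Generator, max_len: int = 200) -> str:
    """Random test sequence over {A, C, H, G} with ligand letters kept sparse."""
    length = int(rng.integers(1, max_len + 1))
    letters = rng.choice(list("ACHG"), size=length, p=[0.4, 0.1, 0.1, 0.4])
    return "".join(letters)


def brute_force_alignment(a: str, b: str) -> tuple[int, int, float]:
    """Enumerate every global alignment; return (score, matches, identity).

    Maximizes (score, matches) lexicographically under match +1 /
    mismatch 0 / gap -1, by exhaustive recursion — exponential, for short
    sequences only.
    """
    best: tuple[int, int] | None = None

    def recurse(i: int, j: int, score: int, matches: int) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            cand = (score, matches)
            if best is None or cand > best:
                best = cand
            return
        if i < len(a) and j < len(b):
            hit = a[i] == b[j]
            recurse(i + 1, j + 1, score + (1 if hit else 0), matches + int(hit))
        if i < len(a):
            recurse(i + 1, j, score - 1, matches)
        if j < len(b):
            recurse(i, j + 1, score - 1, matches)

    recurse(0, 0, 0, 0)
    assert best is not None
    score, matches = best
    gaps = matches - score
    length = (len(a) + len(b) + gaps) // 2
    return score, matches, matches / length


def brute_force_venn_cells(
    membership: dict[str, set[str]], stresses: tuple[str, ...]
) -> dict[tuple[str, ...], set[str]]:
    """Exact-membership cells by direct set algebra over all 2^k - 1 subsets."""
    from itertools import combinations

    universe = set().union(*membership.values()) if membership else set()
    cells: dict[tuple[str, ...], set[str]] = {}
    for k in range(1, len(stresses) + 1):
        for subset in combinations(stresses, k):
            inside = set(universe)
            for s in subset:
                inside &= membership[s]
            for s in stresses:
                if s not in subset:
                    inside -= membership[s]
            if inside:
                cells[subset] = inside
    return cells


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def octet_record() -> ProteinRecord:
    """Hand-constructed protein with exactly one RING-H2 octet.

    Ligands at 4, 7, 17, 19, 22, 25, 30, 33 (residues CCCHHCCC, spacers
    2, 9, 1, 2, 2, 4, 2) — verified against the brute-force enumerator.
    """
    return ProteinRecord("p1", "", "MAACAACAAAAAAAAACAHAAHAACAAAACAACKK")
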