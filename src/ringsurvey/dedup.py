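"""Deterministic redundancy collapse for candidate protein sets.

Replaces ad-hoc manual deduplication of gene-family candidates with a
defined, reproducible procedure:

1. exact duplicates (identical sequences) collapse to the lexicographically
   smallest id;
2. near-duplicates — pairs with global-alignment identity >= ``threshold``
   and mutual coverage >= ``min_coverage`` — are clustered by single
   linkage and each cluster collapses to its longest member (ties: smallest
   id).

Identity uses a global dynamic-programming alignment with match +1,
mismatch 0 and linear gap -1, refined to the score-optimal alignment with
the maximum number of identical pairs.  That refinement makes the identity
fraction unique: with score ``S`` and ``m`` identical pairs fixed, the gap
count is ``g = m - S`` and the alignment length ``L = (|a| + |b| + g) / 2``,
so ``identity = m / L`` does not depend on traceback tie-breaks.

Candidate near-duplicate pairs are prescreened with a banded edit-distance
bound before the exact DP: any pair at identity >= t has an alignment whose
non-identical columns each cost one edit, hence
``edit_distance <= (1 - t) * (|a| + |b|)``.  The screen therefore never
discards a qualifying pair and the final decision is always made by the
exact DP.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Iterable, Sequence

import edlib
import pandas as pd

from .errors import ValidationError
from .io import ProteinRecord

EXACT = "exact-duplicate"
NEAR = "near-duplicate"


@dataclass(frozen=True)
class AlignmentStats:
    """Summary of the optimal (max-score, then max-match) global alignment."""

    score: int
    matches: int
    gap_columns: int
    length: int

    @property
    def identity(self) -> float:
        return self.matches / self.length if self.length else 0.0

    @property
    def aligned_columns(self) -> int:
        return self.length - self.gap_columns


def global_alignment_stats(
    a: str, b: str, *, match: int = 1, mismatch: int = 0, gap: int = -1
) -> AlignmentStats:
    """Global DP maximizing (score, identical pairs) lexicographically."""
    if not a or not b:
        raise ValidationError("cannot align an empty sequence")
    la, lb = len(a), len(b)
    # DP rows hold (score, matches) tuples; lexicographic max is the update rule.
    prev = [(j * gap, 0) for j in range(lb + 1)]
    for i in range(1, la + 1):
        ai = a[i - 1]
        cur = [(i * gap, 0)] + [(0, 0)] * lb
        prev_row = prev
        for j in range(1, lb + 1):
            sub = match if ai == b[j - 1] else mismatch
            ds, dm = prev_row[j - 1]
            diag = (ds + sub, dm + (1 if ai == b[j - 1] else 0))
            us, um = prev_row[j]
            up = (us + gap, um)
            ls, lm = cur[j - 1]
            left = (ls + gap, lm)
            best = diag
            if up > best:
                best = up
            if left > best:
                best = left
            cur[j] = best
        prev = cur
    score, matches = prev[lb]
    gaps = matches - score if match == 1 and mismatch == 0 and gap == -1 else None
    if gaps is None:
        raise ValidationError("alignment statistics require the default scoring scheme")
    length = (la + lb + gaps) // 2
    return AlignmentStats(score=score, matches=matches, gap_columns=gaps, length=length)


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical aligned pairs over alignment length, in [0, 1]."""
    return global_alignment_stats(a, b).identity


def _mutual_coverage(stats: AlignmentStats, la: int, lb: int) -> float:
    cols = stats.aligned_columns
    return min(cols / la, cols / lb)


@dataclass(frozen=True)
class DedupReport:
    """Outcome of :func:`collapse`.

    ``removed`` maps each discarded id to its reason and the kept id it was
    collapsed into; kept and removed ids partition the input and no removed
    id points at another removed id.
    """

    kept_ids: tuple[str, ...]
    removed: tuple[tuple[str, str, str], ...]  # (id, reason, collapsed_into)
    threshold: float
    min_coverage: float

    def to_frame(self) -> pd.DataFrame:
        rows = [{"id": i, "status": "kept", "reason": "", "collapsed_into": ""} for i in self.kept_ids]
        rows += [
            {"id": i, "status": "removed", "reason": r, "collapsed_into": into}
            for i, r, into in self.removed
        ]
        return pd.DataFrame(rows, columns=["id", "status", "reason", "collapsed_into"])


def _near_duplicate_pairs(
    records: Sequence[ProteinRecord], threshold: float, min_coverage: float
) -> list[tuple[str, str]]:
    pairs = []
    for i in range(len(records)):
        a = records[i]
        for j in range(i + 1, len(records)):
            b = records[j]
            bound = ceil((1.0 - threshold) * (len(a) + len(b)))
            res = edlib.align(a.sequence, b.sequence, mode="NW", task="distance", k=bound)
            if res["editDistance"] == -1:
                continue
            stats = global_alignment_stats(a.sequence, b.sequence)
            if stats.identity >= threshold and _mutual_coverage(
                stats, len(a), len(b)
            ) >= min_coverage:
                pairs.append((a.id, b.id))
    return pairs


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {i: i for i in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller id becomes the root
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def collapse(
    records: Sequence[ProteinRecord],
    threshold: float = 0.99,
    min_coverage: float = 0.9,
) -> tuple[list[ProteinRecord], DedupReport]:
    """Collapse exact and near-duplicate records; idempotent and order-independent.

    Returns the kept records (input order preserved) and a
    :class:`DedupReport` accounting for every input id.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValidationError(f"identity threshold must be in (0, 1], got {threshold}")
    if not 0.0 <= min_coverage <= 1.0:
        raise ValidationError(f"min_coverage must be in [0, 1], got {min_coverage}")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate record ids: {dup}")

    # stage 1: exact duplicates -> lexicographically smallest id survives
    by_seq: dict[str, list[ProteinRecord]] = {}
    for rec in records:
        by_seq.setdefault(rec.sequence, []).append(rec)
    removed: dict[str, tuple[str, str]] = {}
    survivors: list[ProteinRecord] = []
    for rec in records:
        group = by_seq[rec.sequence]
        keeper = min(g.id for g in group)
        if rec.id == keeper:
            survivors.append(rec)
        else:
            removed[rec.id] = (EXACT, keeper)

    # stage 2: near-duplicate single-linkage clusters -> longest member survives
    ordered = sorted(survivors, key=lambda r: r.id)
    pairs = _near_duplicate_pairs(ordered, threshold, min_coverage)
    uf = _UnionFind([r.id for r in ordered])
    for a, b in pairs:
        uf.union(a, b)
    clusters: dict[str, list[ProteinRecord]] = {}
    for rec in ordered:
        clusters.setdefault(uf.find(rec.id), []).append(rec)
    rep_of: dict[str, str] = {}
    for members in clusters.values():
        rep = min(members, key=lambda r: (-len(r), r.id)).id
        for rec in members:
            rep_of[rec.id] = rep
    kept: list[ProteinRecord] = []
    for rec in survivors:
        rep = rep_of[rec.id]
        if rec.id == rep:
            kept.append(rec)
        else:
            removed[rec.id] = (NEAR, rep)

    # re-point exact-duplicate removals whose keeper was itself collapsed
    final: list[tuple[str, str, str]] = []
    for rid, (reason, into) in removed.items():
        while into in removed:
            into = removed[into][1]
        final.append((rid, reason, into))
    final.sort()
    report = DedupReport(
        kept_ids=tuple(r.id for r in kept),
        removed=tuple(final),
        threshold=threshold,
        min_coverage=min_coverage,
    )
    assert len(report.kept_ids) + len(report.removed) == len(records)
    return kept, report
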