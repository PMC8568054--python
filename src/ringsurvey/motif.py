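"""Locate RING zinc-finger metal-ligand octets in protein sequences.

A RING domain coordinates two zinc ions through eight Cys/His residues
("metal ligands" M1..M8).  An :class:`OctetGrammar` fixes the residue set
allowed at each ligand position and an integer interval for each of the
seven spacers (residues strictly between consecutive ligands).  The default
grammar follows the canonical RING consensus

    C-X2-C-X(9..39)-C-X(1..3)-[CH]-X(2..3)-[CH]-X2-C-X(4..48)-C-X(1..6)-C

with Cys fixed at positions 1, 2, 3, 6, 7 and 8 and Cys-or-His at 4 and 5;
the bound on the final spacer is kept wide so that HC-subfamily spacing is
decided downstream by the subtype classifier.  ``X`` (unknown residue) never
matches a ligand position: an unknown residue cannot be confirmed as
Cys/His, so calls stay conservative.

Scanning enumerates every octet compatible with the grammar (exhaustive,
equivalent to naive backtracking over all C/H index combinations) and then
resolves redundancy to one deterministic call per domain region while
keeping genuinely disjoint domains.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import ValidationError
from .io import DomainHit, ProteinRecord

logger = logging.getLogger(__name__)

_LIGAND_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class OctetGrammar:
    """Residue sets for M1..M8 and [min, max] spacer bounds for s1..s7."""

    residues: tuple[frozenset[str], ...]
    spacers: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.residues) != 8:
            raise ValidationError("grammar needs exactly 8 ligand residue sets")
        if len(self.spacers) != 7:
            raise ValidationError("grammar needs exactly 7 spacer intervals")
        for i, rs in enumerate(self.residues, start=1):
            if not rs:
                raise ValidationError(f"empty residue set at ligand position M{i}")
            bad = set(rs) - _LIGAND_ALPHABET
            if bad:
                raise ValidationError(
                    f"M{i}: ligand residues must be standard amino acids, got {sorted(bad)}"
                )
        for i, (lo, hi) in enumerate(self.spacers, start=1):
            if not (0 <= lo <= hi):
                raise ValidationError(f"spacer s{i}: invalid interval [{lo}, {hi}]")

    def to_dict(self) -> dict:
        return {
            "residues": ["".join(sorted(rs)) for rs in self.residues],
            "spacers": [list(s) for s in self.spacers],
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "OctetGrammar":
        return cls(
            residues=tuple(frozenset(r) for r in data["residues"]),
            spacers=tuple((int(lo), int(hi)) for lo, hi in data["spacers"]),
        )


#: canonical RING consensus; every value overridable through the run config
DEFAULT_GRAMMAR = OctetGrammar(
    residues=(
        frozenset("C"),
        frozenset("C"),
        frozenset("C"),
        frozenset("CH"),
        frozenset("CH"),
        frozenset("C"),
        frozenset("C"),
        frozenset("C"),
    ),
    spacers=((2, 2), (9, 39), (1, 3), (2, 3), (2, 2), (4, 48), (1, 6)),
)


@dataclass(frozen=True)
class RingMatch:
    """One located metal-ligand octet; coordinates 1-based inclusive."""

    protein_id: str
    positions: tuple[int, int, int, int, int, int, int, int]
    residues: str

    def __post_init__(self) -> None:
        if len(self.positions) != 8 or len(self.residues) != 8:
            raise ValidationError("a RING match has exactly 8 ligand positions/residues")
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValidationError("ligand positions must be strictly increasing")

    @property
    def spacers(self) -> tuple[int, ...]:
        return tuple(
            b - a - 1 for a, b in zip(self.positions, self.positions[1:])
        )

    @property
    def span(self) -> tuple[int, int]:
        return (self.positions[0], self.positions[-1])

    @property
    def spacer_sum(self) -> int:
        return sum(self.spacers)


def _candidate_index(sequence: str) -> dict[str, list[int]]:
    """1-based positions of each residue letter (ligand candidates)."""
    idx: dict[str, list[int]] = {}
    for i, aa in enumerate(sequence, start=1):
        idx.setdefault(aa, []).append(i)
    return idx


def scan_octets(
    record: ProteinRecord,
    grammar: OctetGrammar = DEFAULT_GRAMMAR,
    *,
    resolve: bool = True,
) -> list[RingMatch]:
    """Find RING octets in one protein.

    With ``resolve=False`` every grammar-compatible octet is returned (the
    raw enumeration); with the default ``resolve=True`` redundancy is
    collapsed to one call per domain region (see :func:`resolve_matches`).
    Matches are ordered by M1 position.
    """
    seq = record.sequence
    n = len(seq)
    by_letter = _candidate_index(seq)
    # sorted candidate positions per ligand slot
    slots: list[list[int]] = []
    for rs in grammar.residues:
        merged = sorted(p for aa in rs for p in by_letter.get(aa, []))
        slots.append(merged)
    if any(not s for s in slots):
        return []

    raw: list[tuple[int, ...]] = []
    spacers = grammar.spacers

    def extend(prefix: list[int], slot: int) -> None:
        if slot == 8:
            raw.append(tuple(prefix))
            return
        lo_sp, hi_sp = spacers[slot - 1]
        prev = prefix[-1]
        lo_pos = prev + lo_sp + 1
        hi_pos = prev + hi_sp + 1
        cands = slots[slot]
        for k in range(bisect_left(cands, lo_pos), bisect_right(cands, hi_pos)):
            prefix.append(cands[k])
            extend(prefix, slot + 1)
            prefix.pop()

    for start in slots[0]:
        extend([start], 1)

    matches = [
        RingMatch(record.id, pos, "".join(seq[p - 1] for p in pos)) for pos in raw
    ]
    if resolve:
        matches = resolve_matches(matches)
    matches.sort(key=lambda m: m.positions)
    return matches


def resolve_matches(matches: Sequence[RingMatch]) -> list[RingMatch]:
    """Collapse redundant octets to one deterministic call per domain region.

    Among raw matches sharing the same M1, the smallest total spacer sum
    wins (ties: lexicographically smallest ligand-position tuple).  Among
    the survivors, overlapping spans (span intersection non-empty) are
    resolved greedily: leftmost-starting first, then smallest spacer sum,
    then lexicographic position tuple.  Disjoint domains all survive.
    """
    best_by_start: dict[int, RingMatch] = {}
    for m in matches:
        key = m.positions[0]
        cur = best_by_start.get(key)
        if cur is None or (m.spacer_sum, m.positions) < (cur.spacer_sum, cur.positions):
            best_by_start[key] = m
    kept: list[RingMatch] = []
    for m in sorted(
        best_by_start.values(),
        key=lambda m: (m.positions[0], m.spacer_sum, m.positions),
    ):
        lo, hi = m.span
        if all(hi < k.span[0] or lo > k.span[1] for k in kept):
            kept.append(m)
    kept.sort(key=lambda m: m.positions)
    return kept


def scan_proteome(
    records: Sequence[ProteinRecord],
    grammar: OctetGrammar = DEFAULT_GRAMMAR,
    *,
    hits: Sequence[DomainHit] | None = None,
    flank: int = 10,
) -> dict[str, list[RingMatch]]:
    """Scan many proteins; only ids with >= 1 match appear, sorted by id.

    If ``hits`` is given, scanning is restricted to the hit envelopes
    extended by ``flank`` residues on each side (see :func:`filter_by_hits`);
    an *empty* hit collection means nothing to scan.
    """
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate protein ids in proteome: {dup}")
    if hits is not None:
        windows = filter_by_hits(records, hits, flank)
        out: dict[str, list[RingMatch]] = {}
        for window in windows:
            found = scan_octets(window.as_record(), grammar, resolve=False)
            if found:
                shifted = [
                    RingMatch(
                        window.protein_id,
                        tuple(p + window.offset for p in m.positions),
                        m.residues,
                    )
                    for m in found
                ]
                out.setdefault(window.protein_id, []).extend(shifted)
        return {
            pid: resolve_matches(ms) for pid, ms in sorted(out.items())
        }
    result: dict[str, list[RingMatch]] = {}
    for rec in sorted(records, key=lambda r: r.id):
        found = scan_octets(rec, grammar)
        if found:
            result[rec.id] = found
    return result


@dataclass(frozen=True)
class ScanWindow:
    """A sub-sequence of a protein selected by a domain hit (plus flank).

    ``offset`` is added to window-local 1-based coordinates to recover
    full-sequence coordinates.
    """

    protein_id: str
    sequence: str
    offset: int  # full-sequence position of window residue 1, minus 1

    def as_record(self) -> ProteinRecord:
        return ProteinRecord(self.protein_id, "", self.sequence)


def filter_by_hits(
    records: Sequence[ProteinRecord],
    hits: Sequence[DomainHit],
    flank: int = 10,
) -> list[ScanWindow]:
    """Restrict proteins to hit envelopes +/- ``flank`` residues.

    Overlapping or adjacent envelopes on the same protein are merged into a
    single window.  Hits referencing unknown proteins are skipped with a
    warning.  An empty hit list yields no windows (scanning skipped),
    which is logged.
    """
    if flank < 0:
        raise ValidationError("flank must be non-negative")
    by_id = {r.id: r for r in records}
    if not hits:
        logger.warning("no domain hits supplied; restricted scan selects nothing")
        return []
    intervals: dict[str, list[tuple[int, int]]] = {}
    for hit in hits:
        rec = by_id.get(hit.protein_id)
        if rec is None:
            logger.warning("hit references unknown protein %r; skipped", hit.protein_id)
            continue
        lo = max(1, hit.envelope_start - flank)
        hi = min(len(rec), hit.envelope_end + flank)
        if hit.envelope_end > len(rec):
            raise ValidationError(
                f"hit on {hit.protein_id!r} ends at {hit.envelope_end} but the "
                f"protein has only {len(rec)} residues"
            )
        intervals.setdefault(hit.protein_id, []).append((lo, hi))
    windows: list[ScanWindow] = []
    for pid in sorted(intervals):
        rec = by_id[pid]
        merged: list[list[int]] = []
        for lo, hi in sorted(intervals[pid]):
            if merged and lo <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        for lo, hi in merged:
            windows.append(ScanWindow(pid, rec.sequence[lo - 1 : hi], lo - 1))
    return windows


def matches_to_rows(matches_by_protein: Mapping[str, Sequence[RingMatch]]) -> list[dict]:
    """Flatten scan output into TSV-ready row dicts (subtype left blank)."""
    rows = []
    for pid in sorted(matches_by_protein):
        for m in matches_by_protein[pid]:
            row = {"protein_id": pid}
            for i, p in enumerate(m.positions, start=1):
                row[f"m{i}"] = p
            row["residues"] = m.residues
            row["subtype"] = ""
            rows.append(row)
    return rows
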