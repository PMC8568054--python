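"""Stress-responsive gene calling and Venn set decomposition.

A gene is *responsive* to a stress when its |log2 treatment/control ratio|
reaches the threshold (default 1, i.e. a twofold change) at **any**
timepoint of that stress; the boundary is inclusive because "twofold"
states no strictness.  Responsive sets across k stresses (default the four
of the survey: cold, salt, drought, MeJA) are decomposed into their
2^k - 1 exact-membership Venn cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import ValidationError
from .io import ExpressionMatrix

DEFAULT_STRESSES = ("cold", "salt", "drought", "MeJA")
MAX_VENN_SETS = 6


def log2_ratio(treatment: float, control: float, pseudocount: float = 0.1) -> float:
    """log2((treatment + pseudocount) / (control + pseudocount)).

    The pseudocount (expression units) guards against zeros; it must be
    positive whenever either value is zero.
    """
    if treatment < 0 or control < 0:
        raise ValidationError("expression values must be non-negative")
    if pseudocount < 0:
        raise ValidationError("pseudocount must be non-negative")
    if pseudocount == 0 and (treatment == 0 or control == 0):
        raise ValidationError(
            "zero expression value requires a positive pseudocount"
        )
    return math.log2((treatment + pseudocount) / (control + pseudocount))


@dataclass(frozen=True)
class StressCall:
    """Responsiveness of one gene under one stress."""

    gene: str
    stress: str
    log2_ratios: tuple[tuple[str, float], ...]  # (timepoint, ratio), time order
    responsive: bool
    direction: str  # up | down | mixed | none
    max_abs_log2: float


def call_responsive(
    matrix: ExpressionMatrix,
    gene: str,
    stress: str,
    threshold_log2: float = 1.0,
    pseudocount: float = 0.1,
) -> StressCall:
    """Twofold-at-any-timepoint rule for one gene under one stress.

    ``direction`` is ``up`` if every timepoint reaching the threshold is
    up, ``down`` if every one is down, ``mixed`` otherwise, ``none`` when
    not responsive.
    """
    if threshold_log2 < 0:
        raise ValidationError("threshold_log2 must be non-negative")
    cells = matrix.cell_values(gene, stress)
    ratios = tuple(
        (row.timepoint, log2_ratio(row.treatment, row.control, pseudocount))
        for row in cells.itertuples()
    )
    qualifying = [r for _, r in ratios if abs(r) >= threshold_log2]
    responsive = bool(qualifying)
    if not responsive:
        direction = "none"
    elif all(r > 0 for r in qualifying):
        direction = "up"
    elif all(r < 0 for r in qualifying):
        direction = "down"
    else:
        direction = "mixed"
    max_abs = max((abs(r) for _, r in ratios), default=0.0)
    return StressCall(gene, stress, ratios, responsive, direction, max_abs)


def call_matrix(
    matrix: ExpressionMatrix,
    genes: Sequence[str] | None = None,
    stresses: Sequence[str] | None = None,
    threshold_log2: float = 1.0,
    pseudocount: float = 0.1,
) -> list[StressCall]:
    """Apply :func:`call_responsive` over genes x stresses (sorted by gene, stress order kept)."""
    genes = sorted(genes) if genes is not None else matrix.genes
    stresses = list(stresses) if stresses is not None else matrix.stresses
    unknown = [s for s in stresses if s not in matrix.stresses]
    if unknown:
        raise ValidationError(f"stresses absent from expression matrix: {unknown}")
    return [
        call_responsive(matrix, g, s, threshold_log2, pseudocount)
        for g in genes
        for s in stresses
    ]


@dataclass(frozen=True)
class VennSummary:
    """Exact-membership decomposition of responsive sets across stresses.

    ``cells`` maps each non-empty stress subset (tuple in canonical stress
    order) to the sorted genes responsive to exactly that subset.  Cells
    are disjoint and their sizes sum to the size of the union of the
    responsive sets.
    """

    stresses: tuple[str, ...]
    cells: dict[tuple[str, ...], tuple[str, ...]]

    @staticmethod
    def cell_key(subset: Iterable[str]) -> str:
        return "+".join(subset)

    @property
    def per_stress_counts(self) -> dict[str, int]:
        counts = {s: 0 for s in self.stresses}
        for subset, genes in self.cells.items():
            for s in subset:
                counts[s] += len(genes)
        return counts

    @property
    def exclusive_counts(self) -> dict[str, int]:
        return {s: len(self.cells.get((s,), ())) for s in self.stresses}

    @property
    def all_intersection_count(self) -> int:
        return len(self.cells.get(tuple(self.stresses), ()))

    @property
    def union_size(self) -> int:
        return sum(len(g) for g in self.cells.values())

    @property
    def single_stress_total(self) -> int:
        return sum(self.exclusive_counts.values())

    def genes_in_cell(self, subset: Iterable[str]) -> list[str]:
        key = tuple(s for s in self.stresses if s in set(subset))
        return list(self.cells.get(key, ()))

    def to_dict(self) -> dict:
        return {
            "stresses": list(self.stresses),
            "per_stress_counts": self.per_stress_counts,
            "exclusive_counts": self.exclusive_counts,
            "all_intersection_count": self.all_intersection_count,
            "single_stress_total": self.single_stress_total,
            "union_size": self.union_size,
            "cells": {
                self.cell_key(subset): list(genes)
                for subset, genes in sorted(
                    self.cells.items(), key=lambda kv: (len(kv[0]), kv[0])
                )
            },
        }


def venn_decompose(
    calls: Sequence[StressCall], stresses: Sequence[str] | None = None
) -> VennSummary:
    """Decompose responsive calls into exact-membership Venn cells.

    Every stress must cover the identical gene set; up to ``MAX_VENN_SETS``
    stresses are supported (2^k - 1 cells).
    """
    if stresses is None:
        stresses = list(dict.fromkeys(c.stress for c in calls))
    stresses = tuple(stresses)
    if not stresses:
        return VennSummary(stresses=(), cells={})
    if len(stresses) > MAX_VENN_SETS:
        raise ValidationError(
            f"Venn decomposition supports at most {MAX_VENN_SETS} stresses"
        )
    genes_by_stress: dict[str, set[str]] = {s: set() for s in stresses}
    responsive: dict[str, set[str]] = {s: set() for s in stresses}
    for c in calls:
        if c.stress not in genes_by_stress:
            continue
        genes_by_stress[c.stress].add(c.gene)
        if c.responsive:
            responsive[c.stress].add(c.gene)
    reference = genes_by_stress[stresses[0]]
    for s in stresses[1:]:
        if genes_by_stress[s] != reference:
            missing = sorted(reference ^ genes_by_stress[s])
            raise ValidationError(
                f"gene sets differ between stresses (e.g. {missing[:5]}); "
                "Venn decomposition needs identical coverage"
            )
    cells: dict[tuple[str, ...], list[str]] = {}
    for gene in reference:
        subset = tuple(s for s in stresses if gene in responsive[s])
        if subset:
            cells.setdefault(subset, []).append(gene)
    return VennSummary(
        stresses=stresses,
        cells={k: tuple(sorted(v)) for k, v in cells.items()},
    )


def select_candidates(summary: VennSummary, mode: str) -> list[str]:
    """Pull a sorted gene list out of a :class:`VennSummary`.

    Modes: ``all_four``/``intersection`` (responsive to every stress),
    ``union`` (responsive to any), ``exclusive:<stress>``, and
    ``cell:<s1+s2+...>`` (exact membership).
    """
    if mode in ("all_four", "intersection"):
        return list(summary.cells.get(tuple(summary.stresses), ()))
    if mode == "union":
        return sorted(g for genes in summary.cells.values() for g in genes)
    if mode.startswith("exclusive:"):
        stress = mode.split(":", 1)[1]
        if stress not in summary.stresses:
            raise ValidationError(f"unknown stress {stress!r} in mode {mode!r}")
        return list(summary.cells.get((stress,), ()))
    if mode.startswith("cell:"):
        wanted = mode.split(":", 1)[1].split("+")
        unknown = [s for s in wanted if s not in summary.stresses]
        if unknown:
            raise ValidationError(f"unknown stresses {unknown} in mode {mode!r}")
        return summary.genes_in_cell(wanted)
    raise ValidationError(f"unknown selection mode {mode!r}")


def calls_to_rows(calls: Sequence[StressCall]) -> list[dict]:
    """Flatten calls into TSV-ready row dicts (one row per gene x stress x timepoint)."""
    rows = []
    for c in calls:
        for timepoint, ratio in c.log2_ratios:
            rows.append(
                {
                    "gene": c.gene,
                    "stress": c.stress,
                    "timepoint": timepoint,
                    "log2_ratio": round(ratio, 6),
                    "responsive": c.responsive,
                    "direction": c.direction,
                    "max_abs_log2": round(c.max_abs_log2, 6),
                }
            )
    return rows
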