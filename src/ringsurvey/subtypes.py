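"""RING subtype classification.

Subtypes are distinguished by the residues at metal-ligand positions 4 and
5 and, within the His4/Cys5 subfamily, by the length of the final spacer
(between ligands 7 and 8):

==========  ====  ====  ==================
subtype     M4    M5    spacer s7
==========  ====  ====  ==================
RING-H2     H     H     any
RING-HCa    H     C     2
RING-HCb    H     C     4
RING-C2     C     C     any
RING-v      C     H     any
RING-G      H     C     not 2 and not 4
==========  ====  ====  ==================

RING-G has no published signature; its row here is a provisional catch-all
for the remaining His4/Cys5 spacing and is config-replaceable.  Rules are
evaluated in listed order and the first matching row wins, so user-edited
tables with overlapping rows stay unambiguous (overlaps are additionally
reported by :func:`find_overlaps`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import ValidationError
from .motif import DEFAULT_GRAMMAR, OctetGrammar, RingMatch

UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class SpacerConstraint:
    """Allowed or forbidden lengths for one spacer."""

    allowed: frozenset[int] | None = None
    forbidden: frozenset[int] | None = None

    def __post_init__(self) -> None:
        if (self.allowed is None) == (self.forbidden is None):
            raise ValidationError(
                "spacer constraint needs exactly one of allowed/forbidden"
            )

    def satisfied(self, length: int) -> bool:
        if self.allowed is not None:
            return length in self.allowed
        return length not in self.forbidden  # type: ignore[operator]

    def to_dict(self) -> dict:
        if self.allowed is not None:
            return {"in": sorted(self.allowed)}
        return {"not_in": sorted(self.forbidden)}  # type: ignore[arg-type]

    @classmethod
    def from_dict(cls, data: Mapping) -> "SpacerConstraint":
        if "in" in data:
            return cls(allowed=frozenset(int(v) for v in data["in"]))
        if "not_in" in data:
            return cls(forbidden=frozenset(int(v) for v in data["not_in"]))
        raise ValidationError(f"spacer constraint needs 'in' or 'not_in': {data}")


@dataclass(frozen=True)
class SignatureRule:
    """One subtype signature: required M4/M5 residues plus spacer constraints.

    ``spacer_constraints`` is keyed by 1-based spacer index (s1..s7).
    """

    name: str
    m4: frozenset[str]
    m5: frozenset[str]
    spacer_constraints: tuple[tuple[int, SpacerConstraint], ...] = ()

    def matches(self, match: RingMatch) -> bool:
        if match.residues[3] not in self.m4 or match.residues[4] not in self.m5:
            return False
        spacers = match.spacers
        return all(
            con.satisfied(spacers[idx - 1]) for idx, con in self.spacer_constraints
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "m4": "".join(sorted(self.m4)),
            "m5": "".join(sorted(self.m5)),
            "spacers": {str(i): c.to_dict() for i, c in self.spacer_constraints},
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "SignatureRule":
        return cls(
            name=str(data["name"]),
            m4=frozenset(data["m4"]),
            m5=frozenset(data["m5"]),
            spacer_constraints=tuple(
                (int(i), SpacerConstraint.from_dict(c))
                for i, c in sorted(data.get("spacers", {}).items())
            ),
        )


class SignatureTable:
    """Ordered, first-match-wins list of :class:`SignatureRule` rows."""

    def __init__(self, rules: Sequence[SignatureRule]):
        names = [r.name for r in rules]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate subtype names in signature table: {names}")
        self.rules: tuple[SignatureRule, ...] = tuple(rules)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.rules]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignatureTable):
            return NotImplemented
        return self.rules == other.rules

    def __hash__(self) -> int:
        return hash(self.rules)

    def to_dict(self) -> dict:
        return {"rules": [r.to_dict() for r in self.rules]}

    @classmethod
    def from_dict(cls, data: Mapping) -> "SignatureTable":
        return cls([SignatureRule.from_dict(r) for r in data["rules"]])


DEFAULT_SIGNATURES = SignatureTable(
    [
        SignatureRule("RING-H2", frozenset("H"), frozenset("H")),
        SignatureRule(
            "RING-HCa",
            frozenset("H"),
            frozenset("C"),
            ((7, SpacerConstraint(allowed=frozenset({2}))),),
        ),
        SignatureRule(
            "RING-HCb",
            frozenset("H"),
            frozenset("C"),
            ((7, SpacerConstraint(allowed=frozenset({4}))),),
        ),
        SignatureRule("RING-C2", frozenset("C"), frozenset("C")),
        SignatureRule("RING-v", frozenset("C"), frozenset("H")),
        SignatureRule(
            "RING-G",
            frozenset("H"),
            frozenset("C"),
            ((7, SpacerConstraint(forbidden=frozenset({2, 4}))),),
        ),
    ]
)


def classify_match(match: RingMatch, table: SignatureTable = DEFAULT_SIGNATURES) -> str:
    """First signature row matching (M4, M5, spacer constraints); else ``unclassified``."""
    for rule in table.rules:
        if rule.matches(match):
            return rule.name
    return UNCLASSIFIED


@dataclass(frozen=True)
class FamilySummary:
    """Per-subtype composition at domain and at protein level.

    Domain-level counts every classified octet; protein-level counts each
    protein once per subtype it carries (a multi-domain protein with two
    subtypes appears under both).  Percentages are the domain-level share
    of all classified domains.
    """

    domain_counts: dict[str, int]
    protein_counts: dict[str, int]
    total_domains: int
    total_proteins: int

    @property
    def total_classified_domains(self) -> int:
        return sum(v for k, v in self.domain_counts.items() if k != UNCLASSIFIED)

    @property
    def percentages(self) -> dict[str, float]:
        total = self.total_classified_domains
        if total == 0:
            return {k: 0.0 for k in self.domain_counts if k != UNCLASSIFIED}
        return {
            k: 100.0 * v / total
            for k, v in self.domain_counts.items()
            if k != UNCLASSIFIED
        }

    def to_dict(self) -> dict:
        return {
            "domain_counts": dict(sorted(self.domain_counts.items())),
            "protein_counts": dict(sorted(self.protein_counts.items())),
            "total_domains": self.total_domains,
            "total_proteins": self.total_proteins,
            "percentages": {
                k: round(v, 2) for k, v in sorted(self.percentages.items())
            },
        }


def classify_proteome(
    matches_by_protein: Mapping[str, Sequence[RingMatch]],
    table: SignatureTable = DEFAULT_SIGNATURES,
) -> tuple[dict[str, list[tuple[RingMatch, str]]], FamilySummary]:
    """Annotate every match with its subtype and summarize family composition."""
    annotated: dict[str, list[tuple[RingMatch, str]]] = {}
    domain_counts: dict[str, int] = {}
    protein_counts: dict[str, int] = {}
    n_domains = 0
    for pid in sorted(matches_by_protein):
        labelled = [
            (m, classify_match(m, table)) for m in matches_by_protein[pid]
        ]
        annotated[pid] = labelled
        n_domains += len(labelled)
        for _, name in labelled:
            domain_counts[name] = domain_counts.get(name, 0) + 1
        for name in sorted({name for _, name in labelled}):
            protein_counts[name] = protein_counts.get(name, 0) + 1
    summary = FamilySummary(
        domain_counts=domain_counts,
        protein_counts=protein_counts,
        total_domains=n_domains,
        total_proteins=len(annotated),
    )
    return annotated, summary


def proteins_of_subtype(
    annotated: Mapping[str, Sequence[tuple[RingMatch, str]]], subtype: str
) -> list[str]:
    """Sorted ids of proteins carrying >= 1 domain of ``subtype``."""
    return sorted(
        pid
        for pid, labelled in annotated.items()
        if any(name == subtype for _, name in labelled)
    )


def find_overlaps(
    table: SignatureTable, grammar: OctetGrammar = DEFAULT_GRAMMAR
) -> list[tuple[str, str, tuple[str, str, int]]]:
    """Report rule pairs that both accept some (M4, M5, s7) combination.

    Exhaustively enumerates the grammar's M4/M5 residue sets and s7 range.
    Constraints on spacers other than s7 are ignored here (none of the
    default rules use them).  Used to warn when a user edits the table into
    overlapping rows; first-match-wins keeps behaviour deterministic anyway.
    """
    lo, hi = grammar.spacers[6]
    overlaps = []
    for i, a in enumerate(table.rules):
        for b in table.rules[i + 1 :]:
            for m4 in sorted(grammar.residues[3]):
                for m5 in sorted(grammar.residues[4]):
                    for s7 in range(lo, hi + 1):
                        a_con = dict(a.spacer_constraints)
                        b_con = dict(b.spacer_constraints)
                        a_ok = (
                            m4 in a.m4
                            and m5 in a.m5
                            and (7 not in a_con or a_con[7].satisfied(s7))
                        )
                        b_ok = (
                            m4 in b.m4
                            and m5 in b.m5
                            and (7 not in b_con or b_con[7].satisfied(s7))
                        )
                        if a_ok and b_ok:
                            overlaps.append((a.name, b.name, (m4, m5, s7)))
    return overlaps
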