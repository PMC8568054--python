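"""End-to-end orchestration: scan -> classify -> dedup -> stress -> Venn -> report.

A :class:`RunConfig` (loadable from YAML) names the inputs and every
threshold; :func:`run_pipeline` executes the stages, writes all
machine-readable outputs into the output directory and returns a
:class:`RunReport` whose stage counts are checked for mutual consistency.
Re-running with identical config and inputs produces byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .dedup import collapse
from .errors import RingSurveyError, ValidationError
from .io import read_expression_table, read_fasta, read_hmmer_domtbl
from .motif import DEFAULT_GRAMMAR, OctetGrammar, scan_proteome
from .stress import DEFAULT_STRESSES, call_matrix, calls_to_rows, venn_decompose
from .subtypes import (
    DEFAULT_SIGNATURES,
    SignatureTable,
    classify_proteome,
    find_overlaps,
    proteins_of_subtype,
)

logger = logging.getLogger(__name__)

H2 = "RING-H2"


@dataclass(frozen=True)
class RunConfig:
    """Full parameterization of one pipeline run."""

    fasta: str
    outdir: str
    expression: str | None = None
    domtbl: str | None = None
    flank: int = 10
    grammar: OctetGrammar = DEFAULT_GRAMMAR
    signatures: SignatureTable = DEFAULT_SIGNATURES
    dedup_threshold: float = 0.99
    dedup_min_coverage: float = 0.9
    threshold_log2: float = 1.0
    pseudocount: float = 0.1
    gene_subset: str = "H2"  # H2 | all
    stresses: tuple[str, ...] = DEFAULT_STRESSES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gene_subset not in ("H2", "all"):
            raise ValidationError(f"gene_subset must be 'H2' or 'all', got {self.gene_subset!r}")

    def to_dict(self) -> dict:
        return {
            "fasta": self.fasta,
            "outdir": self.outdir,
            "expression": self.expression,
            "domtbl": self.domtbl,
            "flank": self.flank,
            "grammar": self.grammar.to_dict(),
            "signatures": self.signatures.to_dict(),
            "dedup_threshold": self.dedup_threshold,
            "dedup_min_coverage": self.dedup_min_coverage,
            "threshold_log2": self.threshold_log2,
            "pseudocount": self.pseudocount,
            "gene_subset": self.gene_subset,
            "stresses": list(self.stresses),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        data = dict(data)
        if "grammar" in data and data["grammar"] is not None:
            data["grammar"] = OctetGrammar.from_dict(data["grammar"])
        else:
            data.pop("grammar", None)
        if "signatures" in data and data["signatures"] is not None:
            data["signatures"] = SignatureTable.from_dict(data["signatures"])
        else:
            data.pop("signatures", None)
        if "stresses" in data:
            data["stresses"] = tuple(data["stresses"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open("r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @property
    def config_hash(self) -> str:
        # the hash covers analysis parameters and inputs, not where output goes
        payload = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        canonical = json.dumps(payload, sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class RunReport:
    """Per-stage counts of one pipeline run, mutually consistent."""

    n_input_proteins: int
    n_candidate_proteins: int
    n_duplicates_removed: int
    n_ring_proteins: int
    subtype_protein_counts: dict[str, int]
    subtype_domain_counts: dict[str, int]
    per_stress_responsive: dict[str, int]
    all_stress_intersection: int
    exclusive_counts: dict[str, int]
    single_stress_total: int
    n_expression_genes: int
    version: str
    config_hash: str

    def validate(self) -> None:
        if self.n_candidate_proteins > self.n_input_proteins:
            raise ValidationError("more candidates than input proteins")
        if self.n_ring_proteins + self.n_duplicates_removed != self.n_candidate_proteins:
            raise ValidationError("dedup counts do not conserve candidates")
        if sum(self.subtype_domain_counts.values()) < self.n_ring_proteins:
            raise ValidationError("fewer classified domains than RING proteins")
        if self.single_stress_total != sum(self.exclusive_counts.values()):
            raise ValidationError("exclusive cells do not sum to single-stress total")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _write_tsv(rows: Sequence[dict], columns: Sequence[str], path: Path) -> None:
    pd.DataFrame(list(rows), columns=list(columns)).to_csv(path, sep="\t", index=False)


def _write_json(data: dict, path: Path) -> None:
    path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full survey; writes outputs under ``config.outdir``.

    Outputs: ``matches.tsv`` (subtype-annotated octets), ``family_summary.json``,
    ``dedup_report.tsv``, and — when an expression table is configured —
    ``stress_calls.tsv`` and ``venn.json``; always ``report.json``.
    Any stage failure aborts with the stage name in the message.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name: str):
        logger.info("[%s] starting", name)
        return name

    # --- scan ---------------------------------------------------------
    name = stage("scan")
    try:
        records = read_fasta(config.fasta)
        hits = read_hmmer_domtbl(config.domtbl) if config.domtbl else None
        matches = scan_proteome(
            records, config.grammar, hits=hits, flank=config.flank
        )
    except RingSurveyError as exc:
        raise RingSurveyError(f"stage {name}: {exc}") from exc

    # --- classify -----------------------------------------------------
    name = stage("classify")
    overlaps = find_overlaps(config.signatures, config.grammar)
    if overlaps:
        logger.warning(
            "signature table rows overlap (first-match-wins applies): %s",
            sorted({(a, b) for a, b, _ in overlaps}),
        )
    annotated, _pre_summary = classify_proteome(matches, config.signatures)

    # --- dedup --------------------------------------------------------
    name = stage("dedup")
    by_id = {r.id: r for r in records}
    candidates = [by_id[pid] for pid in sorted(matches)]
    try:
        kept, dedup_report = collapse(
            candidates, config.dedup_threshold, config.dedup_min_coverage
        )
    except RingSurveyError as exc:
        raise RingSurveyError(f"stage {name}: {exc}") from exc
    kept_ids = {r.id for r in kept}
    final_matches = {pid: ms for pid, ms in matches.items() if pid in kept_ids}
    final_annotated, summary = classify_proteome(final_matches, config.signatures)

    match_rows = []
    for pid in sorted(final_annotated):
        for m, label in final_annotated[pid]:
            row = {"protein_id": pid}
            row.update({f"m{i}": p for i, p in enumerate(m.positions, start=1)})
            row["residues"] = m.residues
            row["subtype"] = label
            match_rows.append(row)
    _write_tsv(
        match_rows,
        ["protein_id"] + [f"m{i}" for i in range(1, 9)] + ["residues", "subtype"],
        outdir / "matches.tsv",
    )
    _write_json(summary.to_dict(), outdir / "family_summary.json")
    dedup_report.to_frame().to_csv(outdir / "dedup_report.tsv", sep="\t", index=False)

    # --- stress + venn ------------------------------------------------
    per_stress: dict[str, int] = {}
    exclusive: dict[str, int] = {}
    all_intersection = 0
    single_total = 0
    n_expr_genes = 0
    if config.expression:
        name = stage("stress")
        try:
            matrix = read_expression_table(config.expression)
            unknown = [s for s in matrix.stresses if s not in config.stresses]
            if unknown:
                raise ValidationError(
                    f"expression table contains unknown stresses {unknown}; "
                    f"configured stresses are {list(config.stresses)}"
                )
            if config.gene_subset == "H2":
                subset = [
                    g
                    for g in proteins_of_subtype(final_annotated, H2)
                    if g in set(matrix.genes)
                ]
            else:
                subset = matrix.genes
            n_expr_genes = len(subset)
            calls = call_matrix(
                matrix,
                genes=subset,
                stresses=[s for s in config.stresses if s in matrix.stresses],
                threshold_log2=config.threshold_log2,
                pseudocount=config.pseudocount,
            )
            venn = venn_decompose(calls)
        except RingSurveyError as exc:
            raise RingSurveyError(f"stage {name}: {exc}") from exc
        _write_tsv(
            calls_to_rows(calls),
            [
                "gene",
                "stress",
                "timepoint",
                "log2_ratio",
                "responsive",
                "direction",
                "max_abs_log2",
            ],
            outdir / "stress_calls.tsv",
        )
        _write_json(venn.to_dict(), outdir / "venn.json")
        per_stress = venn.per_stress_counts
        exclusive = venn.exclusive_counts
        all_intersection = venn.all_intersection_count
        single_total = venn.single_stress_total

    report = RunReport(
        n_input_proteins=len(records),
        n_candidate_proteins=len(candidates),
        n_duplicates_removed=len(dedup_report.removed),
        n_ring_proteins=summary.total_proteins,
        subtype_protein_counts=dict(sorted(summary.protein_counts.items())),
        subtype_domain_counts=dict(sorted(summary.domain_counts.items())),
        per_stress_responsive=per_stress,
        all_stress_intersection=all_intersection,
        exclusive_counts=exclusive,
        single_stress_total=single_total,
        n_expression_genes=n_expr_genes,
        version=__version__,
        config_hash=config.config_hash,
    )
    report.validate()
    _write_json(report.to_dict(), outdir / "report.json")
    return report
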