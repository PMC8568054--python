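"""Readers and writers for every external format the pipeline touches.

Formats
-------
* protein FASTA (multi-line, ``>`` headers) — via Bio.SeqIO
* HMMER3 per-domain tabular output (``--domtblout``)
* expression TSV with header ``gene  stress  timepoint  control  treatment``
* qPCR Ct TSV with header ``sample  gene  replicate  ct``

All tabular files are tab-separated UTF-8 with a mandatory header and ``.``
as the decimal point.  Readers validate strictly and never silently drop
rows: every malformed row raises with its line number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from .errors import FormatError, ValidationError

#: the 20 standard amino acids plus X (unknown residue)
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
VALID_SEQUENCE_LETTERS = AMINO_ACIDS | {"X"}

EXPRESSION_COLUMNS = ["gene", "stress", "timepoint", "control", "treatment"]
CT_COLUMNS = ["sample", "gene", "replicate", "ct"]


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence.

    ``sequence`` is upper-case over the 20 standard letters plus ``X``; a
    single trailing ``*`` (translated stop codon) is stripped on read.
    """

    id: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("protein record with empty id")
        if not self.sequence:
            raise ValidationError(f"protein {self.id!r}: empty sequence")
        bad = sorted(set(self.sequence) - VALID_SEQUENCE_LETTERS)
        if bad:
            raise ValidationError(
                f"protein {self.id!r}: invalid residue letters {''.join(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DomainHit:
    """One per-domain hit from a HMMER3 ``--domtblout`` file.

    Coordinates are the *envelope* columns, 1-based inclusive.
    """

    protein_id: str
    model_name: str
    envelope_start: int
    envelope_end: int
    independent_evalue: float
    score: float

    def __post_init__(self) -> None:
        if self.envelope_start < 1 or self.envelope_start > self.envelope_end:
            raise ValidationError(
                f"hit on {self.protein_id!r}: bad envelope "
                f"{self.envelope_start}..{self.envelope_end}"
            )
        if self.independent_evalue < 0:
            raise ValidationError(
                f"hit on {self.protein_id!r}: negative E-value "
                f"{self.independent_evalue}"
            )


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file into a list of :class:`ProteinRecord`.

    Wrapped sequence lines are concatenated and upper-cased; record order is
    preserved.  A single trailing ``*`` is stripped.  Duplicate ids, empty
    sequences and residue letters outside the 20 standard amino acids + X
    raise :class:`FormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"FASTA file not found: {path}")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        bad = sorted(set(seq) - VALID_SEQUENCE_LETTERS)
        if bad:
            raise FormatError(
                f"{path}: record {rec.id!r} contains non-amino-acid "
                f"characters {''.join(bad)!r}"
            )
        description = rec.description[len(rec.id) :].strip()
        records.append(ProteinRecord(rec.id, description, seq))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as wrapped FASTA (inverse of :func:`read_fasta`)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# HMMER3 domtblout: 22 whitespace-delimited fields + free-text description.
_DOMTBL_MIN_FIELDS = 23
_DOMTBL_COL = {
    "target_name": 0,
    "query_name": 3,
    "i_evalue": 12,
    "dom_score": 13,
    "env_from": 19,
    "env_to": 20,
}


def read_hmmer_domtbl(path: str | Path) -> list[DomainHit]:
    """Parse a HMMER3 ``--domtblout`` file into :class:`DomainHit` objects.

    One hit per non-comment line; ``#`` lines are skipped.  Malformed lines
    raise :class:`FormatError` with their line number.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"domtblout file not found: {path}")
    hits: list[DomainHit] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.split(None, _DOMTBL_MIN_FIELDS - 1)
            if len(fields) < _DOMTBL_MIN_FIELDS - 1:
                raise FormatError(
                    f"{path}:{lineno}: expected >= {_DOMTBL_MIN_FIELDS - 1} "
                    f"domtblout fields, found {len(fields)}"
                )
            try:
                hit = DomainHit(
                    protein_id=fields[_DOMTBL_COL["target_name"]],
                    model_name=fields[_DOMTBL_COL["query_name"]],
                    envelope_start=int(fields[_DOMTBL_COL["env_from"]]),
                    envelope_end=int(fields[_DOMTBL_COL["env_to"]]),
                    independent_evalue=float(fields[_DOMTBL_COL["i_evalue"]]),
                    score=float(fields[_DOMTBL_COL["dom_score"]]),
                )
            except (ValueError, ValidationError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    return hits


class ExpressionMatrix:
    """Control/treatment expression per (gene, stress, timepoint).

    Thin validated wrapper around a long-form :class:`pandas.DataFrame`
    with columns ``gene, stress, timepoint, control, treatment``.  Within
    each stress every gene must carry the same timepoint set; values are
    non-negative finite expression units (e.g. FPKM).
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in EXPRESSION_COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"expression table missing columns {missing}")
        frame = frame.loc[:, EXPRESSION_COLUMNS].copy()
        frame["gene"] = frame["gene"].astype(str)
        frame["stress"] = frame["stress"].astype(str)
        frame["timepoint"] = frame["timepoint"].astype(str)
        for col in ("control", "treatment"):
            frame[col] = pd.to_numeric(frame[col], errors="raise")
            if not frame[col].map(math.isfinite).all():
                raise ValidationError(f"expression column {col!r} has non-finite values")
            if (frame[col] < 0).any():
                bad = frame.loc[frame[col] < 0].iloc[0]
                raise ValidationError(
                    f"negative {col} value for gene {bad['gene']!r}, "
                    f"stress {bad['stress']!r}, timepoint {bad['timepoint']!r}"
                )
        dup = frame.duplicated(subset=["gene", "stress", "timepoint"])
        if dup.any():
            bad = frame.loc[dup].iloc[0]
            raise ValidationError(
                f"duplicate expression row: gene {bad['gene']!r}, "
                f"stress {bad['stress']!r}, timepoint {bad['timepoint']!r}"
            )
        # every gene within a stress must have an identical timepoint set
        for stress, sub in frame.groupby("stress", sort=False):
            tp_all = list(dict.fromkeys(sub["timepoint"]))
            counts = sub.groupby("gene")["timepoint"].apply(frozenset)
            full = frozenset(tp_all)
            missing_cells = [
                f"({g}, {stress}, {t})"
                for g, tps in counts.items()
                if tps != full
                for t in sorted(full - tps)
            ]
            if missing_cells:
                raise ValidationError(
                    f"missing expression cells: {', '.join(missing_cells[:10])}"
                    + ("..." if len(missing_cells) > 10 else "")
                )
        self._frame = frame.reset_index(drop=True)

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame.copy()

    @property
    def genes(self) -> list[str]:
        return sorted(self._frame["gene"].unique())

    @property
    def stresses(self) -> list[str]:
        return list(dict.fromkeys(self._frame["stress"]))

    def timepoints(self, stress: str) -> list[str]:
        sub = self._frame.loc[self._frame["stress"] == stress, "timepoint"]
        if sub.empty:
            raise ValidationError(f"unknown stress {stress!r}")
        return list(dict.fromkeys(sub))

    def cell_values(self, gene: str, stress: str) -> pd.DataFrame:
        """Timepoint-ordered (timepoint, control, treatment) rows for one gene/stress."""
        sub = self._frame[
            (self._frame["gene"] == gene) & (self._frame["stress"] == stress)
        ]
        if sub.empty:
            raise ValidationError(f"no expression data for gene {gene!r} under {stress!r}")
        order = {t: i for i, t in enumerate(self.timepoints(stress))}
        return (
            sub.assign(_o=sub["timepoint"].map(order))
            .sort_values("_o")
            .drop(columns="_o")
            .reset_index(drop=True)
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        a = self._frame.sort_values(["gene", "stress", "timepoint"]).reset_index(drop=True)
        b = other._frame.sort_values(["gene", "stress", "timepoint"]).reset_index(drop=True)
        return a.equals(b)


def read_expression_table(path: str | Path) -> ExpressionMatrix:
    """Read the expression TSV dialect (header ``gene stress timepoint control treatment``)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"expression table not found: {path}")
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse TSV: {exc}") from exc
    if list(frame.columns) != EXPRESSION_COLUMNS:
        raise FormatError(
            f"{path}: expected header {EXPRESSION_COLUMNS}, found {list(frame.columns)}"
        )
    try:
        return ExpressionMatrix(frame)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.frame.to_csv(path, sep="\t", index=False)


class CtTable:
    """Replicate qPCR Ct values with a designated housekeeping gene and calibrator sample.

    Long-form rows ``(sample, gene, replicate, ct)``; every (sample, gene)
    pair needs >= 1 replicate and the housekeeping gene must be measured in
    every sample.
    """

    def __init__(self, frame: pd.DataFrame, housekeeping: str, calibrator: str):
        missing = [c for c in CT_COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"Ct table missing columns {missing}")
        frame = frame.loc[:, CT_COLUMNS].copy()
        frame["sample"] = frame["sample"].astype(str)
        frame["gene"] = frame["gene"].astype(str)
        frame["replicate"] = pd.to_numeric(frame["replicate"], errors="raise").astype(int)
        frame["ct"] = pd.to_numeric(frame["ct"], errors="raise")
        if not frame["ct"].map(math.isfinite).all():
            raise ValidationError("Ct table contains non-finite Ct values")
        dup = frame.duplicated(subset=["sample", "gene", "replicate"])
        if dup.any():
            bad = frame.loc[dup].iloc[0]
            raise ValidationError(
                f"duplicate Ct row: sample {bad['sample']!r}, gene {bad['gene']!r}, "
                f"replicate {bad['replicate']}"
            )
        samples = list(dict.fromkeys(frame["sample"]))
        hk_samples = set(frame.loc[frame["gene"] == housekeeping, "sample"])
        lacking = [s for s in samples if s not in hk_samples]
        if lacking:
            raise ValidationError(
                f"housekeeping gene {housekeeping!r} missing for samples {lacking}"
            )
        if calibrator not in samples:
            raise ValidationError(f"calibrator sample {calibrator!r} not in table")
        self._frame = frame.reset_index(drop=True)
        self.housekeeping = housekeeping
        self.calibrator = calibrator

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame.copy()

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self._frame["sample"]))

    @property
    def genes(self) -> list[str]:
        return list(dict.fromkeys(self._frame["gene"]))

    def replicate_cts(self, sample: str, gene: str) -> pd.Series:
        """Ct values for one (sample, gene), indexed by replicate number."""
        sub = self._frame[
            (self._frame["sample"] == sample) & (self._frame["gene"] == gene)
        ]
        if sub.empty:
            raise ValidationError(f"no Ct rows for sample {sample!r}, gene {gene!r}")
        return sub.set_index("replicate")["ct"].sort_index()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CtTable):
            return NotImplemented
        if (self.housekeeping, self.calibrator) != (other.housekeeping, other.calibrator):
            return False
        key = ["sample", "gene", "replicate"]
        a = self._frame.sort_values(key).reset_index(drop=True)
        b = other._frame.sort_values(key).reset_index(drop=True)
        return a.equals(b)


def read_ct_table(path: str | Path, housekeeping: str, calibrator: str) -> CtTable:
    """Read the Ct TSV dialect (header ``sample gene replicate ct``)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"Ct table not found: {path}")
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if list(frame.columns) != CT_COLUMNS:
        raise FormatError(
            f"{path}: expected header {CT_COLUMNS}, found {list(frame.columns)}"
        )
    try:
        return CtTable(frame, housekeeping=housekeeping, calibrator=calibrator)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_ct_table(table: CtTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)
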