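"""Relative qPCR quantification by the 2^-ddCt method.

Per replicate, dCt = Ct_target - Ct_housekeeping; per sample the replicate
dCt values are averaged; ddCt = mean dCt_sample - mean dCt_calibrator and
fold = 2^(-ddCt).  Amplification efficiency is fixed at the classic value
of 2 (one doubling per cycle); no efficiency correction is applied.  The
calibrator sample's fold is exactly 1 by construction, and adding any
constant to all Ct values of a sample (target and housekeeping alike)
leaves its fold unchanged.

Replicate dispersion is reported as the sample standard deviation of the
per-replicate dCt values.  With balanced technical/biological replicate
counts the mean over all replicates equals the mean of per-biological-
replicate means, so a flat replicate index is sufficient.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import mean, stdev
from typing import Sequence

from .errors import ValidationError
from .io import CtTable


@dataclass(frozen=True)
class FoldChangeResult:
    """2^-ddCt quantification of one target gene in one sample."""

    sample: str
    gene: str
    mean_delta_ct: float
    delta_delta_ct: float
    fold: float
    delta_ct_sd: float  # sd of per-replicate dCt (0 with a single replicate)
    n_replicates: int


def _sample_delta_cts(table: CtTable, sample: str, target_gene: str) -> list[float]:
    target = table.replicate_cts(sample, target_gene)
    housekeeping = table.replicate_cts(sample, table.housekeeping)
    if set(target.index) != set(housekeeping.index):
        raise ValidationError(
            f"sample {sample!r}: target and housekeeping replicate indices differ "
            f"({sorted(target.index)} vs {sorted(housekeeping.index)})"
        )
    return [target[r] - housekeeping[r] for r in sorted(target.index)]


def delta_delta_ct(table: CtTable, target_gene: str) -> list[FoldChangeResult]:
    """Quantify ``target_gene`` in every sample relative to the calibrator.

    Returns one :class:`FoldChangeResult` per sample carrying the target,
    calibrator first, then the remaining samples in table order.
    """
    if target_gene not in table.genes:
        raise ValidationError(f"target gene {target_gene!r} not in Ct table")
    samples_with_target = [
        s
        for s in table.samples
        if not table.frame[
            (table.frame["sample"] == s) & (table.frame["gene"] == target_gene)
        ].empty
    ]
    if table.calibrator not in samples_with_target:
        raise ValidationError(
            f"calibrator sample {table.calibrator!r} has no Ct values for "
            f"target {target_gene!r}"
        )
    calibrator_mean = mean(_sample_delta_cts(table, table.calibrator, target_gene))
    ordered = [table.calibrator] + [
        s for s in samples_with_target if s != table.calibrator
    ]
    results = []
    for sample in ordered:
        dcts = _sample_delta_cts(table, sample, target_gene)
        m = mean(dcts)
        ddct = m - calibrator_mean
        results.append(
            FoldChangeResult(
                sample=sample,
                gene=target_gene,
                mean_delta_ct=m,
                delta_delta_ct=ddct,
                fold=2.0 ** (-ddct),
                delta_ct_sd=stdev(dcts) if len(dcts) > 1 else 0.0,
                n_replicates=len(dcts),
            )
        )
    return results


@dataclass(frozen=True)
class TimecourseSummary:
    gene: str
    max_fold: float
    at_timepoint: str


def summarize_timecourse(
    folds: Sequence[tuple[str, float]], gene: str = ""
) -> TimecourseSummary:
    """Maximum fold across a timecourse and its timepoint (ties: earliest).

    ``folds`` is a sequence of (timepoint_label, fold) pairs in time order.
    """
    if not folds:
        raise ValidationError("timecourse needs at least one timepoint")
    best_tp, best_fold = folds[0]
    for tp, fold in folds[1:]:
        if fold > best_fold:
            best_tp, best_fold = tp, fold
    return TimecourseSummary(gene=gene, max_fold=best_fold, at_timepoint=best_tp)


def results_to_rows(results: Sequence[FoldChangeResult]) -> list[dict]:
    return [
        {
            "sample": r.sample,
            "gene": r.gene,
            "mean_delta_ct": round(r.mean_delta_ct, 6),
            "delta_delta_ct": round(r.delta_delta_ct, 6),
            "fold": round(r.fold, 6),
            "delta_ct_sd": round(r.delta_ct_sd, 6),
            "n_replicates": r.n_replicates,
        }
        for r in results
    ]
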