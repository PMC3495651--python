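"""Dataset-level QC and reduction: conditional log transform, range filters,
annotation-coverage filter, replicate averaging.

All thresholds are overridable; the defaults are the standard ones for
normalized microarray compendia: matrices whose values exceed 25 are assumed
linear-scale and log2-transformed, matrices with no value above log2(5000)
or any value above log2(20,000,000) are discarded, and datasets whose probe
annotation covers less than 90% of probes are discarded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionDataset

__all__ = [
    "QcThresholds",
    "QcReport",
    "ConditionMatrix",
    "maybe_log_transform",
    "qc_filter",
    "average_replicates",
    "write_qc_log",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class QcThresholds:
    """Tunable QC constants (defaults match the standard pipeline)."""

    log_trigger: float = 25.0        # any value above this => assume linear scale
    low_signal: float = 5_000.0      # keep only if max > log2(low_signal)
    out_of_range: float = 20_000_000.0   # drop if any value > log2(out_of_range)
    min_coverage: float = 0.90


@dataclass
class QcReport:
    dataset_id: str
    kept: bool
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.kept == (not self.reasons)


@dataclass
class ConditionMatrix:
    """Genes x conditions matrix of per-condition replicate means."""

    dataset_id: str
    genes: list[str]
    conditions: list[str]
    values: np.ndarray
    replicate_counts: dict[str, int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.conditions)):
            raise ValueError(
                f"dataset {self.dataset_id!r}: condition matrix shape "
                f"{self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.conditions)} conditions"
            )


def maybe_log_transform(ds: ExpressionDataset, log_trigger: float = 25.0) -> ExpressionDataset:
    """log2-transform a dataset that looks linear-scale; otherwise no-op.

    The trigger is strict: any finite value > ``log_trigger`` causes the
    whole matrix to be transformed.  Non-positive values cannot be
    log-transformed and become missing (logged).
    """
    finite = np.isfinite(ds.values)
    if not finite.any():
        return ds
    if np.nanmax(ds.values) <= log_trigger:
        return ds
    values = ds.values.copy()
    nonpos = finite & (values <= 0)
    if nonpos.any():
        log.warning(
            "dataset %s: %d non-positive values became missing during log transform",
            ds.dataset_id, int(nonpos.sum()),
        )
        values[nonpos] = np.nan
    with np.errstate(invalid="ignore"):
        values = np.log2(values)
    return ExpressionDataset(
        ds.dataset_id, list(ds.genes), list(ds.samples), values, ds.condition_of,
    )


def qc_filter(
    ds: ExpressionDataset,
    probe_coverage: float = 1.0,
    thresholds: QcThresholds = QcThresholds(),
) -> QcReport:
    """Decide whether a (log-scale) dataset enters map building.

    Reasons accumulate; ``kept`` is true iff none fire:

    * ``low_signal`` — no value above log2(5,000)
    * ``out_of_range`` — one or more values above log2(20,000,000)
    * ``low_annotation_coverage`` — probe coverage below 90%
    * ``too_few_conditions`` — fewer than 2 distinct conditions
    """
    reasons: list[str] = []
    finite = np.isfinite(ds.values)
    vmax = np.max(ds.values[finite]) if finite.any() else -math.inf
    if not vmax > math.log2(thresholds.low_signal):
        reasons.append("low_signal")
    if vmax > math.log2(thresholds.out_of_range):
        reasons.append("out_of_range")
    if probe_coverage < thresholds.min_coverage:
        reasons.append("low_annotation_coverage")
    n_conditions = (
        len(ds.conditions) if ds.condition_of is not None else 0
    )
    if n_conditions < 2:
        reasons.append("too_few_conditions")
    return QcReport(ds.dataset_id, kept=not reasons, reasons=reasons)


def average_replicates(ds: ExpressionDataset) -> ConditionMatrix:
    """Average same-condition replicates into a genes x conditions matrix.

    Missing replicate values are ignored when a condition has several
    replicates; a gene missing its only measurement in a single-replicate
    condition is removed from the whole dataset.
    """
    if ds.condition_of is None:
        raise ValueError(f"dataset {ds.dataset_id!r}: no condition map attached")
    conditions = ds.conditions
    groups: dict[str, list[int]] = {c: [] for c in conditions}
    for j, s in enumerate(ds.samples):
        groups[ds.condition_of[s]].append(j)
    for c, idx in groups.items():
        if not idx:
            raise ValueError(f"dataset {ds.dataset_id!r}: condition {c!r} has no samples")

    n_genes = len(ds.genes)
    means = np.full((n_genes, len(conditions)), np.nan)
    counts = {}
    for k, c in enumerate(conditions):
        block = ds.values[:, groups[c]]
        finite = np.isfinite(block)
        n = finite.sum(axis=1)
        sums = np.where(finite, block, 0.0).sum(axis=1)
        np.divide(sums, n, out=means[:, k], where=n > 0)
        means[n == 0, k] = np.nan
        counts[c] = len(groups[c])

    single = [k for k, c in enumerate(conditions) if counts[c] == 1]
    keep = np.ones(n_genes, dtype=bool)
    if single:
        keep &= ~np.isnan(means[:, single]).any(axis=1)
    if not keep.all():
        log.debug(
            "dataset %s: removed %d genes missing in single-replicate conditions",
            ds.dataset_id, int((~keep).sum()),
        )
    genes = [g for g, k in zip(ds.genes, keep) if k]
    return ConditionMatrix(ds.dataset_id, genes, conditions, means[keep], counts)


def write_qc_log(reports: list[QcReport], path) -> None:
    """TSV audit log: dataset_id, kept, semicolon-joined reasons."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("dataset_id\tkept\treasons\n")
        for r in reports:
            fh.write(f"{r.dataset_id}\t{str(r.kept).lower()}\t{';'.join(r.reasons)}\n")
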