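"""Applying abundance thresholds and the replicate detection-rate filter.

Two filters are provided: the mixture-derived abundance filter (remove every
ASV whose log10 total read count falls below a threshold; equality retains)
and the replicate-based comparison filter (retain only ASVs detected, i.e.
with at least one read, in a minimum fraction of technical replicates —
by default all of them).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .io import ASVTable

__all__ = [
    "FilterReport",
    "ConfusionCounts",
    "abundance_filter",
    "detection_rate_filter",
    "confusion_counts",
]


@dataclass
class ConfusionCounts:
    """Filter outcome against known truth labels.

    ``false_retained`` are artefacts that survived the filter (false
    positives of the study); ``true_removed`` are genuine variants the filter
    discarded (false negatives).
    """

    true_retained: int
    true_removed: int
    false_retained: int
    false_removed: int

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FilterReport:
    """Bookkeeping of one filtering operation."""

    threshold_log10: float | None
    n_input: int
    n_retained: int
    n_removed: int
    retained_ids: list[str]
    removed_ids: list[str]
    confusion: ConfusionCounts | None = field(default=None)

    def __post_init__(self) -> None:
        if self.n_input != self.n_retained + self.n_removed:
            raise ValueError("retained + removed must equal input")
        if set(self.retained_ids) & set(self.removed_ids):
            raise ValueError("retained and removed ids overlap")

    def to_dict(self) -> dict:
        d = {
            "threshold_log10": self.threshold_log10,
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "n_removed": self.n_removed,
            "retained_ids": list(self.retained_ids),
            "removed_ids": list(self.removed_ids),
        }
        if self.confusion is not None:
            d["confusion"] = self.confusion.to_dict()
        return d


def abundance_filter(table: ASVTable, threshold_log10: float) -> tuple[ASVTable, FilterReport]:
    """Retain ASVs with log10(total) at or above the threshold (equality retains)."""
    if not np.isfinite(threshold_log10):
        raise ValueError("threshold must be finite")
    log_tot = np.log10(table.total.astype(float))
    keep = log_tot >= threshold_log10
    filtered = table.select(keep)
    report = FilterReport(
        threshold_log10=float(threshold_log10),
        n_input=table.n_asvs,
        n_retained=int(keep.sum()),
        n_removed=int((~keep).sum()),
        retained_ids=[table.asv_ids[i] for i in np.flatnonzero(keep)],
        removed_ids=[table.asv_ids[i] for i in np.flatnonzero(~keep)],
    )
    return filtered, report


def detection_rate_filter(
    counts, min_rate: float = 1.0, asv_ids: list[str] | None = None
) -> tuple[list[str], FilterReport]:
    """Retain ASVs detected in at least ``min_rate`` of technical replicates.

    ``counts`` is an ASV-by-replicate matrix (or an :class:`ASVTable` whose
    samples are the replicates); "detected" means at least one read.  The
    default ``min_rate=1.0`` keeps only ASVs found in every replicate.
    """
    if isinstance(counts, ASVTable):
        asv_ids = list(counts.asv_ids)
        counts = counts.counts
    counts = np.asarray(counts)
    if counts.ndim != 2 or counts.shape[1] < 1:
        raise ValueError("need an ASV-by-replicate matrix with >= 1 replicate")
    if asv_ids is None:
        asv_ids = [f"asv{i + 1}" for i in range(counts.shape[0])]
    rate = (counts >= 1).mean(axis=1)
    keep = rate >= min_rate
    report = FilterReport(
        threshold_log10=None,
        n_input=counts.shape[0],
        n_retained=int(keep.sum()),
        n_removed=int((~keep).sum()),
        retained_ids=[asv_ids[i] for i in np.flatnonzero(keep)],
        removed_ids=[asv_ids[i] for i in np.flatnonzero(~keep)],
    )
    return report.retained_ids, report


def confusion_counts(report: FilterReport, truth: dict[str, bool]) -> ConfusionCounts:
    """Cross-tabulate a filter outcome against truth labels (True = genuine variant).

    The labels must cover every input ASV; a missing one raises a KeyError
    naming it.  The result is also attached to ``report.confusion``.
    """
    for asv in report.retained_ids + report.removed_ids:
        if asv not in truth:
            raise KeyError(f"no truth label for ASV {asv!r}")
    tr = sum(truth[a] for a in report.retained_ids)
    fr = len(report.retained_ids) - tr
    tm = sum(truth[a] for a in report.removed_ids)
    fm = len(report.removed_ids) - tm
    cc = ConfusionCounts(true_retained=int(tr), true_removed=int(tm),
                         false_retained=int(fr), false_removed=int(fm))
    report.confusion = cc
    return cc
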