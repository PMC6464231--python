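"""Sample- and taxon-level QC cascade and rarefaction.

The cascade mirrors amplicon-study practice for a multi-run MiSeq design
with negative controls, applied in a fixed order:

1. failed sequencing — a patient sample whose raw read count is strictly
   below the largest negative-control read count of its run cannot be
   distinguished from a blank;
2. low preprocessed reads — fewer than ``min_reads`` (default 2,000)
   sequences after quality/chimera filtering;
3. rare-OTU removal — taxa holding strictly less than ``otu_min_frac``
   (default 0.01%) of the grand total over surviving samples;
4. low OTU-table reads — column sum below ``min_reads`` after rare-OTU
   removal;
5. rarefaction of survivors to ``depth`` (default 2,000), a single seeded
   draw without replacement per sample.

A sample failing several criteria is reported under the earliest stage
only, so the exclusion categories are mutually exclusive and
``n_input == n_retained + sum(exclusions)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .containers import (EXCLUSION_ORDER, FormatError, QCStatus,
                         SampleRecord, TaxonCountTable)


class QCError(ValueError):
    """Raised when QC preconditions are violated (e.g. a run lacks controls)."""


@dataclass
class QCReport:
    """Outcome of the QC cascade over one cohort's patient samples."""

    statuses: dict[str, QCStatus]
    n_input: int
    n_retained: int
    exclusions: dict[QCStatus, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total_excluded = sum(self.exclusions.values())
        if self.n_input != self.n_retained + total_excluded:
            raise ValueError(
                f"QC bookkeeping broken: {self.n_input} != "
                f"{self.n_retained} + {total_excluded}")

    @property
    def n_excluded(self) -> int:
        return self.n_input - self.n_retained

    @property
    def percent_excluded(self) -> float:
        return 100.0 * self.n_excluded / self.n_input if self.n_input else 0.0

    def retained_ids(self) -> list[str]:
        return [s for s, st in self.statuses.items()
                if st == QCStatus.PASSED]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"sample_id": s, "qc_status": st.value}
             for s, st in self.statuses.items()])


# ---------------------------------------------------------------------------
# stage 1: failed sequencing vs negative controls

def call_failed_sequencing(
        records: Sequence[SampleRecord]) -> dict[str, QCStatus]:
    """Mark patient samples with raw reads strictly below their run's
    negative-control maximum.

    Every run containing patient samples must carry at least one negative
    control; controls themselves are never marked. Returns statuses only
    for the samples marked failed.
    """
    by_run: dict[str, list[SampleRecord]] = {}
    for rec in records:
        by_run.setdefault(rec.run_id, []).append(rec)
    statuses: dict[str, QCStatus] = {}
    for run_id, run_records in by_run.items():
        controls = [r for r in run_records if r.is_negative_control]
        patients = [r for r in run_records if not r.is_negative_control]
        if not patients:
            continue
        if not controls:
            raise QCError(f"run {run_id!r} has no negative control")
        threshold = max(r.raw_reads for r in controls)
        for rec in patients:
            if rec.raw_reads < threshold:
                statuses[rec.sample_id] = QCStatus.FAILED_SEQUENCING
    return statuses


# ---------------------------------------------------------------------------
# stages 2 and 4: read-depth filters

Stage = Literal["preprocessed", "otu_table"]

_STAGE_STATUS = {
    "preprocessed": QCStatus.LOW_READS_PREPROCESSED,
    "otu_table": QCStatus.LOW_READS_OTU,
}


def filter_low_read_samples(table: TaxonCountTable | None,
                            records: Sequence[SampleRecord],
                            min_reads: int = 2000,
                            stage: Stage = "preprocessed",
                            already_excluded: set[str] | None = None,
                            ) -> dict[str, QCStatus]:
    """Mark patient samples with strictly fewer than ``min_reads`` sequences.

    The ``preprocessed`` stage reads ``preprocessed_reads`` from the
    metadata; the ``otu_table`` stage uses the sample's column sum in the
    current (rare-OTU-filtered) table. Samples in ``already_excluded`` are
    skipped — the cascade reports only the first applicable exclusion.
    """
    if stage not in _STAGE_STATUS:
        raise QCError(f"unknown stage {stage!r}")
    already_excluded = already_excluded or set()
    statuses: dict[str, QCStatus] = {}
    if stage == "otu_table":
        if table is None:
            raise QCError("otu_table stage requires a count table")
        sums = table.sample_sums()
    for rec in records:
        if rec.is_negative_control or rec.sample_id in already_excluded:
            continue
        if stage == "preprocessed":
            depth = rec.preprocessed_reads
        else:
            if rec.sample_id not in sums.index:
                continue
            depth = int(sums[rec.sample_id])
        if depth < min_reads:
            statuses[rec.sample_id] = _STAGE_STATUS[stage]
    return statuses


# ---------------------------------------------------------------------------
# stage 3: rare-OTU removal

def filter_rare_otus(table: TaxonCountTable,
                     frac: float = 0.0001) -> TaxonCountTable:
    """Drop taxa whose grand-total count is strictly below ``frac`` of the
    table's grand total (default 0.01%), computed once over all samples
    given."""
    if table.n_taxa == 0:
        raise QCError("empty table")
    totals = table.taxon_sums()
    grand = int(totals.sum())
    keep = totals >= frac * grand
    return table.select_taxa(list(totals.index[keep]))


# ---------------------------------------------------------------------------
# stage 5: rarefaction

def rarefy(sample_counts, depth: int = 2000,
           seed: int | None = None,
           rng: np.random.Generator | None = None):
    """Subsample a count vector to ``depth`` sequences without replacement.

    A single multivariate-hypergeometric draw (the urn model of pulling
    ``depth`` sequences out of the observed pool); output counts are
    integers summing exactly to ``depth``. Deterministic for a fixed seed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    is_series = isinstance(sample_counts, pd.Series)
    x = np.asarray(sample_counts, dtype=np.int64)
    total = int(x.sum())
    if total < depth:
        raise QCError(
            f"cannot rarefy: sample total {total} below depth {depth}")
    if total == depth:
        out = x.copy()
    else:
        out = rng.multivariate_hypergeometric(x, depth)
    if is_series:
        return pd.Series(out, index=sample_counts.index,
                         name=sample_counts.name)
    return out


# ---------------------------------------------------------------------------
# the full cascade

def run_qc_cascade(table: TaxonCountTable,
                   records: Sequence[SampleRecord],
                   depth: int = 2000,
                   min_reads: int = 2000,
                   otu_min_frac: float = 0.0001,
                   seed: int | None = 0,
                   ) -> tuple[QCReport, TaxonCountTable]:
    """Apply the full QC cascade and rarefy the survivors.

    Returns the per-sample report (patient samples only; negative controls
    are consulted for the failed-sequencing thresholds but never counted)
    and the filtered, rarefied table with only retained patient samples.
    """
    rec_map = {r.sample_id: r for r in records}
    unknown = sorted(set(r.sample_id for r in records
                         if not r.is_negative_control)
                     - set(table.sample_ids))
    if unknown:
        raise QCError(f"metadata samples missing from table: {unknown}")

    patient_ids = [r.sample_id for r in records if not r.is_negative_control]
    statuses: dict[str, QCStatus] = {s: QCStatus.PENDING for s in patient_ids}

    # 1. failed sequencing (needs controls, run-wise)
    statuses.update(call_failed_sequencing(records))
    excluded = {s for s, st in statuses.items() if st != QCStatus.PENDING}

    # 2. preprocessed-read filter
    statuses.update(filter_low_read_samples(
        None, records, min_reads, "preprocessed", excluded))
    excluded = {s for s, st in statuses.items() if st != QCStatus.PENDING}

    # 3. rare-OTU filter over samples surviving the read filters
    survivors = [s for s in patient_ids if s not in excluded]
    working = filter_rare_otus(table.select_samples(survivors), otu_min_frac)

    # 4. OTU-table read filter on the filtered table
    statuses.update(filter_low_read_samples(
        working, [rec_map[s] for s in survivors], min_reads, "otu_table",
        excluded))
    excluded = {s for s, st in statuses.items() if st != QCStatus.PENDING}

    # 5. rarefaction of retained samples
    retained = [s for s in patient_ids if s not in excluded]
    rng = np.random.default_rng(seed)
    working = working.select_samples(retained)
    rarefied = working.counts.copy()
    for sid in retained:
        rarefied[sid] = rarefy(working.counts[sid], depth, rng=rng)
        statuses[sid] = QCStatus.PASSED
    out_table = TaxonCountTable(rarefied, working.lineages)

    exclusions = {cat: sum(1 for st in statuses.values() if st == cat)
                  for cat in EXCLUSION_ORDER}
    report = QCReport(statuses=statuses, n_input=len(patient_ids),
                      n_retained=len(retained), exclusions=exclusions)
    return report, out_table
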