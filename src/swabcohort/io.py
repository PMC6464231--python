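"""Readers and writers for the pipeline's plain-text interchange formats.

All tables are tab-separated. The count table has one row per taxon:
``taxon_id <TAB> lineage <TAB> <sample counts...>``. Trees are newick.
Every writer round-trips bit-identically with its reader for integer
counts and within 1e-9 for branch lengths.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import (DistanceMatrix, ExposureInterval, FormatError,
                         PhyloTree, QCStatus, SampleRecord, TaxonCountTable,
                         records_by_id)
from .taxonomy import Lineage

LINEAGE_COLUMN = "lineage"
TAXON_COLUMN = "taxon_id"


# ---------------------------------------------------------------------------
# count tables

def read_count_table(path: str | Path) -> TaxonCountTable:
    """Read a taxa × samples count table.

    The first column is the taxon id, the second the rank-prefixed lineage
    string, the remaining columns are per-sample integer counts.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2 or df.columns[0] != TAXON_COLUMN or \
            df.columns[1] != LINEAGE_COLUMN:
        raise FormatError(
            f"{path}: first two columns must be "
            f"{TAXON_COLUMN!r}, {LINEAGE_COLUMN!r}")
    if df[TAXON_COLUMN].isna().any() or df[LINEAGE_COLUMN].isna().any():
        raise FormatError(f"{path}: missing taxon id or lineage")
    taxa = df[TAXON_COLUMN].tolist()
    if len(set(taxa)) != len(taxa):
        raise FormatError(f"{path}: duplicate taxon ids")
    lineages = {t: Lineage.parse(s)
                for t, s in zip(taxa, df[LINEAGE_COLUMN])}
    body = df.drop(columns=[TAXON_COLUMN, LINEAGE_COLUMN])
    try:
        counts = body.astype(np.int64)
    except ValueError as exc:
        raise FormatError(f"{path}: non-integer count ({exc})") from exc
    counts.index = pd.Index(taxa, name=TAXON_COLUMN)
    if counts.size and counts.to_numpy().min() < 0:
        raise FormatError(f"{path}: negative count")
    return TaxonCountTable(counts, lineages)


def write_count_table(table: TaxonCountTable, path: str | Path) -> None:
    out = table.counts.copy()
    out.insert(0, LINEAGE_COLUMN,
               [table.lineages[t].format() for t in table.taxon_ids])
    out.index.name = TAXON_COLUMN
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# sample metadata

_META_COLUMNS = ["sample_id", "patient_id", "day", "run_id",
                 "is_negative_control", "raw_reads", "preprocessed_reads",
                 "qc_status"]


def read_metadata(path: str | Path) -> list[SampleRecord]:
    """Read per-sample metadata records.

    The control flag is 0/1; controls leave patient_id and day empty.
    An unknown or empty qc_status defaults to ``pending``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in _META_COLUMNS[:7] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        is_ctrl = str(row.is_negative_control).strip() in ("1", "True", "true")
        day = None if row.day == "" else int(row.day)
        if not is_ctrl and day is not None and day < 0:
            raise FormatError(f"{path}: negative day for {row.sample_id}")
        status = QCStatus.PENDING
        if "qc_status" in df.columns:
            raw_status = str(getattr(row, "qc_status", "")).strip()
            try:
                status = QCStatus(raw_status)
            except ValueError:
                status = QCStatus.PENDING
        records.append(SampleRecord(
            sample_id=row.sample_id,
            patient_id=row.patient_id or None,
            day=day,
            run_id=row.run_id,
            is_negative_control=is_ctrl,
            raw_reads=int(row.raw_reads),
            preprocessed_reads=int(row.preprocessed_reads),
            qc_status=status,
        ))
    records_by_id(records)  # raises on duplicate sample ids
    return records


def write_metadata(records: Sequence[SampleRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append({
            "sample_id": r.sample_id,
            "patient_id": r.patient_id or "",
            "day": "" if r.day is None else r.day,
            "run_id": r.run_id,
            "is_negative_control": int(r.is_negative_control),
            "raw_reads": r.raw_reads,
            "preprocessed_reads": r.preprocessed_reads,
            "qc_status": r.qc_status.value,
        })
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(path, sep="\t",
                                                     index=False)


# ---------------------------------------------------------------------------
# antibiotic exposure intervals

def read_exposures(path: str | Path) -> list[ExposureInterval]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    needed = ["patient_id", "start_day", "end_day", "agent"]
    missing = [c for c in needed[:3] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing exposure columns {missing}")
    return [ExposureInterval(patient_id=row.patient_id,
                             start_day=int(row.start_day),
                             end_day=int(row.end_day),
                             agent=getattr(row, "agent", ""))
            for row in df.itertuples(index=False)]


def write_exposures(intervals: Sequence[ExposureInterval],
                    path: str | Path) -> None:
    pd.DataFrame(
        [{"patient_id": i.patient_id, "start_day": i.start_day,
          "end_day": i.end_day, "agent": i.agent} for i in intervals],
        columns=["patient_id", "start_day", "end_day", "agent"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# trees

def read_tree(path: str | Path) -> PhyloTree:
    """Read a rooted newick tree with branch lengths."""
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:
        raise FormatError(f"{path}: unparseable newick ({exc})") from exc
    return PhyloTree(tree)


def write_tree(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# distances and reports

def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    dm.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(list(df.index), df.to_numpy(dtype=float))


def write_run_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
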