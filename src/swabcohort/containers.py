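"""Core domain containers for the longitudinal swab-cohort pipeline.

The central object is the :class:`TaxonCountTable` — a taxa × samples
integer count matrix with a taxonomic lineage per taxon. Sample-level
metadata lives in :class:`SampleRecord`, antibiotic courses in
:class:`ExposureInterval`, and the rooted phylogeny (needed for Faith's PD
and weighted UniFrac) in :class:`PhyloTree`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .taxonomy import Lineage


class FormatError(ValueError):
    """Raised when an input file or in-memory structure violates the schema."""


class QCStatus(str, enum.Enum):
    """Fate of a sample in the QC cascade, in cascade order."""

    PENDING = "pending"
    PASSED = "passed"
    FAILED_SEQUENCING = "failed_sequencing"
    LOW_READS_PREPROCESSED = "low_reads_preprocessed"
    LOW_READS_OTU = "low_reads_otu"


#: QC exclusion categories in the order the cascade applies them.
EXCLUSION_ORDER = (
    QCStatus.FAILED_SEQUENCING,
    QCStatus.LOW_READS_PREPROCESSED,
    QCStatus.LOW_READS_OTU,
)


class TaxonCountTable:
    """Taxa × samples non-negative integer counts with per-taxon lineages.

    Parameters
    ----------
    counts
        DataFrame indexed by taxon id, columns are sample ids, values are
        non-negative integers.
    lineages
        Mapping from taxon id to :class:`~swabcohort.taxonomy.Lineage`;
        every taxon in ``counts`` must have one.
    """

    def __init__(self, counts: pd.DataFrame,
                 lineages: Mapping[str, Lineage]) -> None:
        if counts.index.has_duplicates:
            raise FormatError("duplicate taxon ids")
        if counts.columns.has_duplicates:
            raise FormatError("duplicate sample ids")
        arr = counts.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise FormatError("counts must be integral")
            counts = counts.astype(np.int64)
            arr = counts.to_numpy()
        if arr.size and arr.min() < 0:
            raise FormatError("counts must be non-negative")
        missing = [t for t in counts.index if t not in lineages]
        if missing:
            raise FormatError(f"missing lineage for taxa: {missing}")
        self.counts = counts.astype(np.int64)
        self.lineages = {t: lineages[t] for t in counts.index}

    # -- basic accessors ---------------------------------------------------
    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def sample_sums(self) -> pd.Series:
        """Per-sample sequence totals (column sums)."""
        return self.counts.sum(axis=0)

    def taxon_sums(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def select_samples(self, sample_ids: Sequence[str]) -> "TaxonCountTable":
        return TaxonCountTable(self.counts.loc[:, list(sample_ids)],
                               self.lineages)

    def select_taxa(self, taxon_ids: Sequence[str]) -> "TaxonCountTable":
        return TaxonCountTable(self.counts.loc[list(taxon_ids), :],
                               self.lineages)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample proportions; columns with zero total become all-NaN."""
        totals = self.counts.sum(axis=0)
        return self.counts / totals

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TaxonCountTable):
            return NotImplemented
        return (self.counts.equals(other.counts)
                and self.lineages == other.lineages)

    def __repr__(self) -> str:
        return (f"TaxonCountTable({self.n_taxa} taxa x "
                f"{self.n_samples} samples)")


@dataclass
class SampleRecord:
    """Per-sample metadata.

    ``day`` counts days since the patient's baseline (baseline = 0).
    Negative controls carry no patient or day. ``preprocessed_reads`` is the
    read count after quality/chimera filtering and can never exceed
    ``raw_reads``.
    """

    sample_id: str
    patient_id: str | None
    day: int | None
    run_id: str
    is_negative_control: bool = False
    raw_reads: int = 0
    preprocessed_reads: int = 0
    qc_status: QCStatus = QCStatus.PENDING

    def __post_init__(self) -> None:
        if self.is_negative_control:
            if self.patient_id or self.day is not None:
                raise FormatError(
                    f"negative control {self.sample_id} must have no "
                    "patient/day")
        else:
            if not self.patient_id:
                raise FormatError(f"sample {self.sample_id} lacks patient id")
            if self.day is None or self.day < 0:
                raise FormatError(
                    f"sample {self.sample_id}: day must be >= 0")
        if self.raw_reads < 0 or self.preprocessed_reads < 0:
            raise FormatError(
                f"sample {self.sample_id}: read counts must be >= 0")
        if self.preprocessed_reads > self.raw_reads:
            raise FormatError(
                f"sample {self.sample_id}: preprocessed_reads "
                f"({self.preprocessed_reads}) exceeds raw_reads "
                f"({self.raw_reads})")


@dataclass(frozen=True)
class ExposureInterval:
    """One antibiotic course: inclusive administration window in study days."""

    patient_id: str
    start_day: int
    end_day: int
    agent: str = ""

    def __post_init__(self) -> None:
        if self.start_day > self.end_day:
            raise FormatError(
                f"exposure interval for {self.patient_id}: start_day "
                f"{self.start_day} > end_day {self.end_day}")


@dataclass(frozen=True)
class DiversityRecord:
    """Alpha-diversity scores of one sample."""

    sample_id: str
    shannon: float
    inv_simpson: float
    faith_pd: float

    def __post_init__(self) -> None:
        if self.shannon < 0 or self.faith_pd < 0 or self.inv_simpson < 1 - 1e-12:
            raise ValueError(f"invalid diversity record for {self.sample_id}")


class PhyloTree:
    """A rooted phylogeny whose leaves are table taxon ids.

    Wraps an :class:`skbio.TreeNode`; validates that leaf labels are unique
    and branch lengths non-negative (an absent root length is treated as 0).
    """

    def __init__(self, tree: TreeNode) -> None:
        if tree.length is None:
            tree.length = 0.0
        labels = []
        for node in tree.traverse(include_self=True):
            if node.length is None or node.length < 0:
                if node.length is not None and node.length < 0:
                    raise FormatError(
                        f"negative branch length on {node.name!r}")
                raise FormatError(f"missing branch length on {node.name!r}")
            if node.is_tip():
                if not node.name:
                    raise FormatError("unlabeled leaf")
                labels.append(node.name)
        if len(labels) != len(set(labels)):
            raise FormatError("duplicate leaf labels")
        self.tree = tree
        self._leaves = set(labels)

    @property
    def leaf_names(self) -> set[str]:
        return set(self._leaves)

    def total_branch_length(self) -> float:
        return sum(n.length for n in self.tree.traverse(include_self=True))

    def validate_against(self, table: TaxonCountTable) -> None:
        """Every table taxon must map to exactly one leaf."""
        self.validate_against_ids(table.taxon_ids)

    def validate_against_ids(self, taxon_ids: Iterable[str]) -> None:
        missing = sorted(set(taxon_ids) - self._leaves)
        if missing:
            raise FormatError(
                f"{len(missing)} table taxa missing from tree: {missing}")

    def to_newick(self) -> str:
        import io

        buf = io.StringIO()
        self.tree.write(buf, format="newick")
        return buf.getvalue().strip()


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with a zero diagonal."""

    sample_ids: list[str]
    data: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.sample_ids)
        if self.data.shape != (n, n):
            raise FormatError("distance matrix shape mismatch")
        if len(set(self.sample_ids)) != n:
            raise FormatError("duplicate sample ids in distance matrix")
        if not np.allclose(self.data, self.data.T, atol=1e-12):
            raise FormatError("distance matrix not symmetric")
        if np.any(np.diag(self.data) != 0):
            raise FormatError("distance matrix diagonal not zero")
        if self.data.size and self.data.min() < 0:
            raise FormatError("negative distances")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.sample_ids,
                            columns=self.sample_ids)


def records_by_id(records: Iterable[SampleRecord]) -> dict[str, SampleRecord]:
    out: dict[str, SampleRecord] = {}
    for rec in records:
        if rec.sample_id in out:
            raise FormatError(f"sample {rec.sample_id} referenced twice")
        out[rec.sample_id] = rec
    return out
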