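"""Rule-based event calls on relative-abundance profiles.

* Domination: a single taxon holding at least 30% of a sample's sequences
  while being the unique most abundant taxon at its rank.
* Antibiotic exposure: a sample taken during an administration ongoing for
  at least 3 days, or within 2 days after its termination.
* Skin-commensal flags: Corynebacterium / Staphylococcus / Streptococcus
  above 10% ("increased"), dominating, or dominating with an adjacent
  same-patient sample above 10% ("shift").

All rules read compositional (relative) abundances of rarefied counts;
they say nothing about absolute bacterial load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .containers import ExposureInterval, SampleRecord, TaxonCountTable
from .taxonomy import RANKS

logger = logging.getLogger(__name__)

DOMINATION_THRESHOLD = 0.30
INCREASED_THRESHOLD = 0.10
SKIN_GENERA = ("Corynebacterium", "Staphylococcus", "Streptococcus")


@dataclass(frozen=True)
class DominationCall:
    """A sample dominated by one taxon at one rank."""

    sample_id: str
    rank: str                       # "family" or "genus"
    taxon: str
    relative_abundance: float

    def __post_init__(self) -> None:
        if self.relative_abundance < DOMINATION_THRESHOLD:
            raise ValueError(
                f"domination call below threshold: {self.relative_abundance}")


@dataclass(frozen=True)
class SkinFlag:
    """Skin-commensal status of one genus in one sample."""

    sample_id: str
    genus: str
    increased: bool
    dominated: bool
    shift_adjacent: bool

    def __post_init__(self) -> None:
        if self.genus not in SKIN_GENERA:
            raise ValueError(f"not a tracked skin genus: {self.genus}")
        if self.dominated and not self.increased:
            raise ValueError("domination (>=30%) implies increased (>10%)")
        if self.shift_adjacent and not self.dominated:
            raise ValueError("shift_adjacent requires domination")


# ---------------------------------------------------------------------------
# rank aggregation

def aggregate_rank(table: TaxonCountTable, rank: str) -> pd.DataFrame:
    """Sum counts by the named rank and convert to per-sample proportions.

    Unassigned ranks form distinct ``Unclassified <parent>`` bins keyed by
    the nearest classified ancestor. Returns a rank-label × sample
    DataFrame of proportions summing to 1 per sample.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    labels = [table.lineages[t].label_at(rank) for t in table.taxon_ids]
    grouped = table.counts.groupby(pd.Index(labels, name=rank)).sum()
    totals = grouped.sum(axis=0)
    if (totals <= 0).any():
        empty = list(totals.index[totals <= 0])
        raise ValueError(f"samples with zero total counts: {empty}")
    return grouped / totals


# ---------------------------------------------------------------------------
# domination

def call_domination(profile: Mapping[str, float] | pd.Series,
                    threshold: float = DOMINATION_THRESHOLD,
                    sample_id: str = "", rank: str = "genus",
                    ) -> DominationCall | None:
    """Return the dominating taxon of a proportion profile, or None.

    A taxon dominates when its proportion is at least ``threshold`` (>= ,
    inclusive) AND strictly exceeds every other taxon's. A tie at the
    maximum means no unique most-abundant taxon, hence no call (logged).
    """
    series = profile if isinstance(profile, pd.Series) else \
        pd.Series(dict(profile), dtype=float)
    if series.empty:
        return None
    top_value = series.max()
    if top_value < threshold:
        return None
    top_taxa = series.index[series == top_value]
    if len(top_taxa) > 1:
        logger.info("domination tie in sample %s at %.3f among %s; no call",
                    sample_id or "<unnamed>", top_value, list(top_taxa))
        return None
    return DominationCall(sample_id=sample_id, rank=rank,
                          taxon=str(top_taxa[0]),
                          relative_abundance=float(top_value))


def call_dominations(table: TaxonCountTable, rank: str,
                     threshold: float = DOMINATION_THRESHOLD,
                     ) -> list[DominationCall]:
    """Domination calls for every sample of a rarefied table at one rank."""
    profiles = aggregate_rank(table, rank)
    calls = []
    for sid in profiles.columns:
        call = call_domination(profiles[sid], threshold, sample_id=sid,
                               rank=rank)
        if call is not None:
            calls.append(call)
    return calls


# ---------------------------------------------------------------------------
# exposure and baseline labels

def label_exposure(day: int,
                   intervals: Sequence[ExposureInterval],
                   merge_intervals: bool = False) -> bool:
    """Antibiotic-exposure flag for a sample day.

    Exposed iff some administration interval [start, end] satisfies
    (start <= day - 3 and end >= day) — ongoing for at least 3 days — or
    (end < day <= end + 2) — within 2 days after termination. Intervals
    from different agents are tested independently unless
    ``merge_intervals`` merges overlapping/abutting courses first.
    """
    if day < 0:
        raise ValueError("day must be >= 0")
    tested = merge_touching(intervals) if merge_intervals else intervals
    for iv in tested:
        ongoing = iv.start_day <= day - 3 and iv.end_day >= day
        just_ended = iv.end_day < day <= iv.end_day + 2
        if ongoing or just_ended:
            return True
    return False


def merge_touching(
        intervals: Sequence[ExposureInterval]) -> list[ExposureInterval]:
    """Merge overlapping or day-adjacent courses of any agent per patient."""
    out: list[ExposureInterval] = []
    by_patient: dict[str, list[ExposureInterval]] = {}
    for iv in intervals:
        by_patient.setdefault(iv.patient_id, []).append(iv)
    for patient, ivs in by_patient.items():
        ivs = sorted(ivs, key=lambda i: (i.start_day, i.end_day))
        current = ivs[0]
        for nxt in ivs[1:]:
            if nxt.start_day <= current.end_day + 1:
                current = ExposureInterval(
                    patient, current.start_day,
                    max(current.end_day, nxt.end_day),
                    agent=f"{current.agent}+{nxt.agent}")
            else:
                out.append(current)
                current = nxt
        out.append(current)
    return out


def label_baseline(day: int) -> bool:
    """True iff the sample is the patient's day-0 baseline."""
    if day < 0:
        raise ValueError("day must be >= 0")
    return day == 0


def exposure_flags(records: Sequence[SampleRecord],
                   intervals: Sequence[ExposureInterval],
                   merge_intervals: bool = False) -> dict[str, bool]:
    """Per-sample exposure flags for all patient samples."""
    by_patient: dict[str, list[ExposureInterval]] = {}
    for iv in intervals:
        by_patient.setdefault(iv.patient_id, []).append(iv)
    flags = {}
    for rec in records:
        if rec.is_negative_control:
            continue
        flags[rec.sample_id] = label_exposure(
            rec.day, by_patient.get(rec.patient_id, ()), merge_intervals)
    return flags


# ---------------------------------------------------------------------------
# skin commensals

def flag_skin_commensals(genus_profiles: pd.DataFrame,
                         records: Sequence[SampleRecord],
                         threshold_increased: float = INCREASED_THRESHOLD,
                         threshold_domination: float = DOMINATION_THRESHOLD,
                         ) -> list[SkinFlag]:
    """Skin-commensal flags for every retained sample and tracked genus.

    ``genus_profiles`` is the genus-level proportion table of QC-passed
    samples (columns). Per genus: increased iff proportion strictly above
    10%; dominated iff the genus is the sample's (unique) genus-level
    dominator; shift_adjacent iff dominated and the immediately preceding
    or following retained sample of the same patient has that genus above
    10%. Adjacency is by day order among retained samples, regardless of
    calendar gaps; first/last samples have a single neighbor.
    """
    rec_map = {r.sample_id: r for r in records}
    by_patient: dict[str, list[SampleRecord]] = {}
    for sid in genus_profiles.columns:
        rec = rec_map.get(sid)
        if rec is None:
            raise ValueError(f"no metadata for sample {sid}")
        by_patient.setdefault(rec.patient_id, []).append(rec)

    dominators: dict[str, str | None] = {}
    for sid in genus_profiles.columns:
        call = call_domination(genus_profiles[sid], threshold_domination,
                               sample_id=sid, rank="genus")
        dominators[sid] = call.taxon if call else None

    flags: list[SkinFlag] = []
    for patient, recs in by_patient.items():
        ordered = sorted(recs, key=lambda r: r.day)
        if any(b.day < a.day for a, b in zip(ordered, ordered[1:])):
            raise ValueError("unsorted input")  # defensive; sort handles it
        ids = [r.sample_id for r in ordered]
        for pos, sid in enumerate(ids):
            neighbors = [ids[i] for i in (pos - 1, pos + 1)
                         if 0 <= i < len(ids)]
            for genus in SKIN_GENERA:
                prop = float(genus_profiles.at[genus, sid]) \
                    if genus in genus_profiles.index else 0.0
                increased = prop > threshold_increased
                dominated = dominators[sid] == genus
                shift = dominated and any(
                    (float(genus_profiles.at[genus, nb])
                     if genus in genus_profiles.index else 0.0)
                    > threshold_increased
                    for nb in neighbors)
                flags.append(SkinFlag(sample_id=sid, genus=genus,
                                      increased=increased,
                                      dominated=dominated,
                                      shift_adjacent=shift))
    return flags


def dominations_frame(calls: Sequence[DominationCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"sample_id": c.sample_id, "rank": c.rank, "taxon": c.taxon,
          "relative_abundance": c.relative_abundance} for c in calls],
        columns=["sample_id", "rank", "taxon", "relative_abundance"])


def skin_flags_frame(flags: Sequence[SkinFlag]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"sample_id": f.sample_id, "genus": f.genus,
          "increased": f.increased, "dominated": f.dominated,
          "shift_adjacent": f.shift_adjacent} for f in flags],
        columns=["sample_id", "genus", "increased", "dominated",
                 "shift_adjacent"])
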