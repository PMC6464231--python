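"""Synthetic longitudinal swab-cohort generator with ground-truth labels.

Emulates the statistical structure of a hemato-oncology rectal-swab
cohort: ~41 patients sampled weekly (1–30 samples each), baseline-diverse
gut communities, antibiotic-driven diversity loss, Enterococcus-style
domination events, sporadic skin-commensal enrichment episodes, log-normal
sequencing depths, per-run negative controls, and a small fraction of
samples destined to fail QC. Every stochastic choice flows from one seeded
generator, so a fixed seed reproduces the cohort byte for byte.

The community model is Dirichlet-multinomial: each patient draws a
baseline composition from a symmetric Dirichlet, each sample re-draws
around it with a fixed concentration, and counts are multinomial at the
sample's read depth. Antibiotic exposure shrinks the concentrations of
all taxa outside a random per-patient surviving subset, which
mechanically lowers Shannon/PD in exposed samples. Injected events
override the composition after the per-sample draw, so recovering them
downstream is limited only by counting noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import (ExposureInterval, PhyloTree, QCStatus, SampleRecord,
                         TaxonCountTable)
from .taxonomy import Lineage

SKIN_GENERA = ("Corynebacterium", "Staphylococcus", "Streptococcus")
MAX_CONTROL_READS = 298
AGENTS = ("meropenem", "vancomycin", "ciprofloxacin",
          "piperacillin-tazobactam", "ceftriaxone")

# family plan: (family, phylum, class, order, genus slots, extra weight).
# An empty genus slot is an unclassified-genus bin within the family.
# The last three families are the negative-control contaminant pool.
_FAMILY_PLAN = [
    ("Enterococcaceae", "Firmicutes", "Bacilli", "Lactobacillales",
     ["Enterococcus", "Vagococcus"], 3),
    ("Lachnospiraceae", "Firmicutes", "Clostridia", "Clostridiales",
     ["Blautia", "Roseburia", "Coprococcus", ""], 4),
    ("Ruminococcaceae", "Firmicutes", "Clostridia", "Clostridiales",
     ["Ruminococcus", "Faecalibacterium", ""], 4),
    ("Prevotellaceae", "Bacteroidetes", "Bacteroidia", "Bacteroidales",
     ["Prevotella"], 2),
    ("Bacteroidaceae", "Bacteroidetes", "Bacteroidia", "Bacteroidales",
     ["Bacteroides"], 3),
    ("Enterobacteriaceae", "Proteobacteria", "Gammaproteobacteria",
     "Enterobacteriales", ["Escherichia", "Klebsiella", ""], 3),
    ("Veillonellaceae", "Firmicutes", "Negativicutes", "Selenomonadales",
     ["Veillonella"], 2),
    ("Streptococcaceae", "Firmicutes", "Bacilli", "Lactobacillales",
     ["Streptococcus", "Lactococcus"], 2),
    ("Staphylococcaceae", "Firmicutes", "Bacilli", "Bacillales",
     ["Staphylococcus"], 1),
    ("Corynebacteriaceae", "Actinobacteria", "Actinobacteria",
     "Corynebacteriales", ["Corynebacterium"], 1),
    ("Pseudomonadaceae", "Proteobacteria", "Gammaproteobacteria",
     "Pseudomonadales", ["Pseudomonas"], 1),
    ("Comamonadaceae", "Proteobacteria", "Betaproteobacteria",
     "Burkholderiales", ["Comamonas", "Delftia"], 1),
    ("Methylobacteriaceae", "Proteobacteria", "Alphaproteobacteria",
     "Rhizobiales", ["Methylobacterium"], 1),
]

_CONTAMINANT_FAMILIES = {"Pseudomonadaceae", "Comamonadaceae",
                         "Methylobacteriaceae"}

# essential (family, genus) slots filled first so small rosters still carry
# the three skin genera, Enterococcus, a diverse gut core and a contaminant
_ESSENTIAL = [("Enterococcaceae", "Enterococcus"),
              ("Lachnospiraceae", "Blautia"),
              ("Ruminococcaceae", "Ruminococcus"),
              ("Prevotellaceae", "Prevotella"),
              ("Bacteroidaceae", "Bacteroides"),
              ("Enterobacteriaceae", "Escherichia"),
              ("Streptococcaceae", "Streptococcus"),
              ("Staphylococcaceae", "Staphylococcus"),
              ("Corynebacteriaceae", "Corynebacterium"),
              ("Pseudomonadaceae", "Pseudomonas")]


@dataclass(frozen=True)
class TaxonRoster:
    """Fixed taxon layout of a synthetic cohort (ids, lineages, masks)."""

    taxon_ids: tuple[str, ...]
    lineages: dict[str, Lineage]
    families: tuple[str, ...]
    genera: tuple[str, ...]          # aggregation labels (genus rank)
    is_skin: np.ndarray = field(repr=False)
    is_contaminant: np.ndarray = field(repr=False)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)


def build_roster(n_taxa: int = 120) -> TaxonRoster:
    """Deterministic taxon roster partitioned into gut, skin and
    contaminant families."""
    if n_taxa < 10:
        raise ValueError("n_taxa must be >= 10")
    plan = {(f, g): (p, c, o)
            for f, p, c, o, genera, _ in _FAMILY_PLAN for g in genera}
    slots = list(_ESSENTIAL)
    slots += [(f, g) for f, _, _, _, genera, _ in _FAMILY_PLAN
              for g in genera if (f, g) not in _ESSENTIAL]
    # weighted round-robin for the remainder, deterministic
    cycle = [(f, g) for f, _, _, _, genera, w in _FAMILY_PLAN
             for _ in range(w) for g in genera]
    i = 0
    while len(slots) < n_taxa:
        slots.append(cycle[i % len(cycle)])
        i += 1
    slots = slots[:n_taxa]

    ids, lineages, families, genera = [], {}, [], []
    for k, (fam, gen) in enumerate(slots):
        tid = f"OTU_{k + 1:04d}"
        phylum, class_, order = plan[(fam, gen)]
        lin = Lineage(kingdom="Bacteria", phylum=phylum, class_=class_,
                      order=order, family=fam, genus=gen)
        ids.append(tid)
        lineages[tid] = lin
        families.append(fam)
        genera.append(lin.label_at("genus"))
    genera_arr = tuple(genera)
    return TaxonRoster(
        taxon_ids=tuple(ids), lineages=lineages, families=tuple(families),
        genera=genera_arr,
        is_skin=np.array([g in SKIN_GENERA for g in genera_arr]),
        is_contaminant=np.array([f in _CONTAMINANT_FAMILIES
                                 for f in families]),
    )


@dataclass
class SyntheticCohortConfig:
    """Study conditions of the simulated cohort.

    Defaults mirror the emulated study scale: 41 patients, up to 30 weekly
    samples each, ~85k (log-normal) sequences per sample, 2,000-read QC
    thresholds downstream, a 30% domination threshold comfortably below
    the injected 35–90% events.
    """

    n_patients: int = 41
    max_weeks_per_patient: int = 30
    n_taxa: int = 120
    baseline_dirichlet_alpha: float = 0.5
    antibiotic_effect: float = 0.1      # concentration shrink of non-survivors
    survivor_fraction: float = 0.5      # taxa untouched by antibiotics
    p_domination_event: float = 0.25    # per post-baseline sample
    p_skin_episode: float = 0.3         # per patient
    reads_lognormal_mean: float = 11.0  # log-scale; exp(11) ~ 60k reads
    reads_lognormal_sd: float = 0.7
    p_fail_sequencing: float = 0.01
    p_low_reads_preprocessed: float = 0.01
    p_low_reads_otu: float = 0.005
    within_patient_concentration: float = 60.0
    p_week_gap: float = 0.1             # re-admission multi-week holes
    n_runs: int = 5
    seed: int = 0
    # exact planting for QC fixtures (None = stochastic fates above)
    n_samples_target: int | None = None
    n_plant_failed: int | None = None
    n_plant_low_preprocessed: int | None = None
    n_plant_low_otu: int | None = None

    def __post_init__(self) -> None:
        probs = (self.p_domination_event, self.p_skin_episode,
                 self.p_fail_sequencing, self.p_low_reads_preprocessed,
                 self.p_low_reads_otu, self.p_week_gap,
                 self.survivor_fraction)
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if not 0 < self.antibiotic_effect <= 1:
            raise ValueError("antibiotic_effect must lie in (0, 1]")
        if self.n_taxa < 10:
            raise ValueError("n_taxa must be >= 10")
        if self.n_patients < 1 or self.max_weeks_per_patient < 1:
            raise ValueError("need at least one patient and one week")
        if self.n_runs < 1:
            raise ValueError("need at least one run")


@dataclass
class GroundTruth:
    """Injected events and intended fates, keyed by patient sample id."""

    domination_events: dict[str, list[tuple[str, str]]]  # (rank, taxon)
    exposed: dict[str, bool]
    skin_episode: dict[str, str | None]                  # genus or None
    qc_fate: dict[str, QCStatus]

    def validate_ids(self, sample_ids: Sequence[str]) -> None:
        expected = set(sample_ids)
        for name, mapping in (("domination_events", self.domination_events),
                              ("exposed", self.exposed),
                              ("skin_episode", self.skin_episode),
                              ("qc_fate", self.qc_fate)):
            if set(mapping) != expected:
                raise ValueError(f"GroundTruth.{name} keys do not match "
                                 "generated sample ids")


# ---------------------------------------------------------------------------
# tree

def generate_tree(taxon_ids: Sequence[str], seed: int | None = None,
                  families: Sequence[str] | None = None) -> PhyloTree:
    """Random rooted binary tree over ``taxon_ids``.

    Built by random sequential pairwise joins (coalescent-style) with
    exponential(1) branch lengths; when ``families`` is given, family
    mates coalesce within a family subtree before families are joined.
    """
    ids = list(taxon_ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 taxa for a tree")
    if families is not None and len(families) != len(ids):
        raise ValueError("families must align with taxon_ids")
    rng = np.random.default_rng(seed)

    def join(nodes: list[TreeNode]) -> TreeNode:
        nodes = list(nodes)
        while len(nodes) > 1:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            b = nodes.pop(int(j))
            a = nodes.pop(int(i))
            a.length = float(rng.exponential(1.0))
            b.length = float(rng.exponential(1.0))
            nodes.append(TreeNode(children=[a, b]))
        return nodes[0]

    if families is None:
        root = join([TreeNode(name=t) for t in ids])
    else:
        groups: dict[str, list[TreeNode]] = {}
        for tid, fam in zip(ids, families):
            groups.setdefault(fam, []).append(TreeNode(name=tid))
        subtrees = [join(tips) for tips in groups.values()]
        root = join(subtrees) if len(subtrees) > 1 else subtrees[0]
    root.length = 0.0
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# negative controls

def generate_negative_controls(run_ids: Sequence[str],
                               seed: int | None = None,
                               roster: TaxonRoster | None = None,
                               rng: np.random.Generator | None = None,
                               ) -> tuple[list[SampleRecord], pd.DataFrame]:
    """1–3 negative controls per run with 0–298 raw reads each and sparse
    contaminant profiles, as blank swab/reagent sequencing yields."""
    if not run_ids:
        raise ValueError("need at least one run")
    if roster is None:
        roster = build_roster()
    if rng is None:
        rng = np.random.default_rng(seed)
    contam_idx = np.flatnonzero(roster.is_contaminant)
    if contam_idx.size == 0:
        contam_idx = np.arange(roster.n_taxa)
    records, columns = [], {}
    for run_id in run_ids:
        n_controls = int(rng.integers(1, 4))
        for k in range(n_controls):
            raw = int(rng.integers(0, MAX_CONTROL_READS + 1))
            preprocessed = int(round(raw * rng.uniform(0.4, 0.9)))
            weights = rng.dirichlet(np.full(contam_idx.size, 0.3))
            counts = np.zeros(roster.n_taxa, dtype=np.int64)
            counts[contam_idx] = rng.multinomial(preprocessed, weights)
            sid = f"NC_{run_id}_{k + 1}"
            records.append(SampleRecord(
                sample_id=sid, patient_id=None, day=None, run_id=run_id,
                is_negative_control=True, raw_reads=raw,
                preprocessed_reads=preprocessed))
            columns[sid] = counts
    frame = pd.DataFrame(columns, index=pd.Index(roster.taxon_ids,
                                                 name="taxon_id"))
    return records, frame


# ---------------------------------------------------------------------------
# cohort

def _patient_sample_counts(cfg: SyntheticCohortConfig,
                           rng: np.random.Generator) -> list[int]:
    """Samples per patient: 1 + truncated geometric, optionally adjusted to
    hit an exact cohort-wide total."""
    counts = [1 + min(int(rng.geometric(0.1)) - 1,
                      cfg.max_weeks_per_patient - 1)
              for _ in range(cfg.n_patients)]
    if cfg.n_samples_target is not None:
        lo, hi = cfg.n_patients, cfg.n_patients * cfg.max_weeks_per_patient
        if not lo <= cfg.n_samples_target <= hi:
            raise ValueError(
                f"n_samples_target must lie in [{lo}, {hi}]")
        i = 0
        while sum(counts) != cfg.n_samples_target:
            delta = 1 if sum(counts) < cfg.n_samples_target else -1
            new = counts[i % cfg.n_patients] + delta
            if 1 <= new <= cfg.max_weeks_per_patient:
                counts[i % cfg.n_patients] = new
            i += 1
    return counts


def _draw_depth(cfg: SyntheticCohortConfig, rng: np.random.Generator,
                minimum: int = 2100) -> tuple[int, int]:
    """(raw, preprocessed) for a sample meant to pass the read filters;
    the log-normal is truncated below so intended-pass samples pass by
    construction."""
    while True:
        raw = int(round(rng.lognormal(cfg.reads_lognormal_mean,
                                      cfg.reads_lognormal_sd)))
        preprocessed = int(round(raw * rng.uniform(0.80, 0.95)))
        if preprocessed >= minimum:
            return raw, preprocessed


def generate_cohort(cfg: SyntheticCohortConfig
                    ) -> tuple[TaxonCountTable, list[SampleRecord],
                               list[ExposureInterval], PhyloTree,
                               GroundTruth]:
    """Generate one synthetic cohort.

    Returns the count table (patient samples and negative controls as
    columns), sample metadata, antibiotic exposure intervals, the rooted
    taxon phylogeny, and the ground-truth event labels.
    """
    rng = np.random.default_rng(cfg.seed)
    roster = build_roster(cfg.n_taxa)
    tree = generate_tree(roster.taxon_ids,
                         seed=int(rng.integers(2 ** 31)),
                         families=roster.families)

    run_ids = [f"R{r + 1}" for r in range(cfg.n_runs)]
    control_records, control_counts = generate_negative_controls(
        run_ids, roster=roster, rng=rng)
    ctrl_max = {run: max((r.raw_reads for r in control_records
                          if r.run_id == run), default=0)
                for run in run_ids}

    # -- sampling calendar -------------------------------------------------
    counts_per_patient = _patient_sample_counts(cfg, rng)
    patients = [f"P{p + 1:02d}" for p in range(cfg.n_patients)]
    sample_plan: list[tuple[str, str, int]] = []   # (sample_id, patient, day)
    for patient, n_samples in zip(patients, counts_per_patient):
        day = 0
        for k in range(n_samples):
            if k > 0:
                gap_weeks = 1
                if rng.random() < cfg.p_week_gap:
                    gap_weeks += int(rng.integers(1, 4))
                day += 7 * gap_weeks
            sample_plan.append((f"{patient}_d{day:03d}", patient, day))
    n_total = len(sample_plan)
    block = math.ceil(n_total / cfg.n_runs)
    run_of = {sid: run_ids[idx // block]
              for idx, (sid, _, _) in enumerate(sample_plan)}

    # -- antibiotic courses ------------------------------------------------
    last_day = {p: max(d for _, pp, d in sample_plan if pp == p)
                for p in patients}
    untreated = patients[int(rng.integers(cfg.n_patients))]
    intervals: list[ExposureInterval] = []
    for patient in patients:
        if patient == untreated:
            continue
        n_courses = 1 + int(rng.poisson(1.5))
        for _ in range(n_courses):
            start = int(rng.integers(0, max(last_day[patient], 1) + 1))
            duration = int(rng.integers(4, 22))
            intervals.append(ExposureInterval(
                patient_id=patient, start_day=start,
                end_day=start + duration - 1,
                agent=str(rng.choice(AGENTS))))

    def exposed_on(patient: str, day: int) -> bool:
        # same arithmetic the downstream labeler implements: ongoing >= 3
        # days, or within 2 days after termination
        for iv in intervals:
            if iv.patient_id != patient:
                continue
            if (iv.start_day <= day - 3 and iv.end_day >= day) or \
                    (iv.end_day < day <= iv.end_day + 2):
                return True
        return False

    # -- QC fates ----------------------------------------------------------
    sample_ids = [sid for sid, _, _ in sample_plan]
    fate = {sid: QCStatus.PASSED for sid in sample_ids}
    failable = [sid for sid in sample_ids if ctrl_max[run_of[sid]] >= 10]
    if cfg.n_plant_failed is not None or \
            cfg.n_plant_low_preprocessed is not None or \
            cfg.n_plant_low_otu is not None:
        pool = list(sample_ids)
        n_failed = cfg.n_plant_failed or 0
        chosen_failed: list[str] = []
        if n_failed:
            if n_failed > len(failable):
                raise ValueError(
                    "cannot plant that many failed-sequencing samples: "
                    "not enough runs with a usable control threshold")
            pick = rng.choice(len(failable), size=n_failed, replace=False)
            chosen_failed = [failable[int(i)] for i in pick]
        remaining = [s for s in pool if s not in set(chosen_failed)]
        n_low_pre = cfg.n_plant_low_preprocessed or 0
        pick = rng.choice(len(remaining), size=n_low_pre, replace=False)
        chosen_low_pre = [remaining[int(i)] for i in pick]
        remaining = [s for s in remaining if s not in set(chosen_low_pre)]
        n_low_otu = cfg.n_plant_low_otu or 0
        pick = rng.choice(len(remaining), size=n_low_otu, replace=False)
        chosen_low_otu = [remaining[int(i)] for i in pick]
        for s in chosen_failed:
            fate[s] = QCStatus.FAILED_SEQUENCING
        for s in chosen_low_pre:
            fate[s] = QCStatus.LOW_READS_PREPROCESSED
        for s in chosen_low_otu:
            fate[s] = QCStatus.LOW_READS_OTU
    else:
        for sid in sample_ids:
            u = rng.random()
            if u < cfg.p_fail_sequencing and sid in set(failable):
                fate[sid] = QCStatus.FAILED_SEQUENCING
            elif u < cfg.p_fail_sequencing + cfg.p_low_reads_preprocessed:
                fate[sid] = QCStatus.LOW_READS_PREPROCESSED
            elif u < (cfg.p_fail_sequencing + cfg.p_low_reads_preprocessed
                      + cfg.p_low_reads_otu):
                fate[sid] = QCStatus.LOW_READS_OTU

    # -- event schedule ----------------------------------------------------
    focal_eligible = np.flatnonzero(~roster.is_skin & ~roster.is_contaminant)
    enterococcus = np.flatnonzero(
        np.array(roster.genera) == "Enterococcus")
    domination_plan: dict[str, int] = {}        # sample -> focal OTU index
    for sid, _, day in sample_plan:
        if day > 0 and rng.random() < cfg.p_domination_event:
            if enterococcus.size and rng.random() < 0.5:
                focal = int(enterococcus[int(rng.integers(
                    enterococcus.size))])
            else:
                focal = int(focal_eligible[int(rng.integers(
                    focal_eligible.size))])
            domination_plan[sid] = focal

    skin_plan: dict[str, str] = {}              # sample -> genus
    by_patient: dict[str, list[tuple[str, int]]] = {}
    for sid, patient, day in sample_plan:
        by_patient.setdefault(patient, []).append((sid, day))
    for patient in patients:
        if rng.random() >= cfg.p_skin_episode:
            continue
        candidates = [sid for sid, day in by_patient[patient]
                      if day > 0 and sid not in domination_plan]
        if not candidates:
            continue
        genus = str(rng.choice(SKIN_GENERA))
        length = int(rng.integers(1, 4))
        start = int(rng.integers(len(candidates)))
        for sid in candidates[start:start + length]:
            skin_plan[sid] = genus

    # -- compositions and counts -------------------------------------------
    alpha = np.full(roster.n_taxa, cfg.baseline_dirichlet_alpha)
    genera_arr = np.array(roster.genera)
    columns: dict[str, np.ndarray] = {}
    records: list[SampleRecord] = []
    truth_dom: dict[str, list[tuple[str, str]]] = {}
    truth_exposed: dict[str, bool] = {}
    truth_skin: dict[str, str | None] = {}
    kappa = cfg.within_patient_concentration

    for patient, n_samples in zip(patients, counts_per_patient):
        baseline = rng.dirichlet(alpha)
        survivors = rng.random(roster.n_taxa) < cfg.survivor_fraction
        for sid, day in by_patient[patient]:
            exposed = exposed_on(patient, day)
            conc = baseline.copy()
            if exposed:
                conc[~survivors] *= cfg.antibiotic_effect
                conc /= conc.sum()
            comp = rng.dirichlet(np.maximum(kappa * conc, 1e-9))

            truth_dom[sid] = []
            truth_skin[sid] = None
            truth_exposed[sid] = exposed
            if sid in skin_plan:
                genus = skin_plan[sid]
                mask = genera_arr == genus
                target = rng.uniform(0.12, 0.28)
                current = comp[mask].sum()
                if current > 0:
                    comp[mask] *= target / current
                else:
                    comp[np.flatnonzero(mask)[0]] = target
                rest = comp[~mask].sum()
                if rest > 0:
                    comp[~mask] *= (1 - target) / rest
                truth_skin[sid] = genus
            if sid in domination_plan:
                focal = domination_plan[sid]
                target = rng.uniform(0.35, 0.9)
                others = np.ones(roster.n_taxa, dtype=bool)
                others[focal] = False
                rest = comp[others].sum()
                if rest > 0:
                    comp[others] *= (1 - target) / rest
                comp[focal] = target
                lin = roster.lineages[roster.taxon_ids[focal]]
                truth_dom[sid] = [("family", lin.label_at("family")),
                                  ("genus", lin.label_at("genus"))]
            comp = comp / comp.sum()

            sample_fate = fate[sid]
            run = run_of[sid]
            if sample_fate == QCStatus.FAILED_SEQUENCING:
                limit = max(ctrl_max[run], 1)
                raw = int(rng.integers(0, limit))
                preprocessed = int(round(raw * rng.uniform(0.4, 0.9)))
                depth = preprocessed
            elif sample_fate == QCStatus.LOW_READS_PREPROCESSED:
                raw, _ = _draw_depth(cfg, rng)
                preprocessed = int(rng.integers(100, 2000))
                depth = preprocessed
            elif sample_fate == QCStatus.LOW_READS_OTU:
                raw, preprocessed = _draw_depth(cfg, rng)
                depth = int(rng.integers(100, 1900))
            else:
                raw, preprocessed = _draw_depth(cfg, rng)
                depth = preprocessed
            columns[sid] = rng.multinomial(depth, comp)
            records.append(SampleRecord(
                sample_id=sid, patient_id=patient, day=day, run_id=run,
                raw_reads=raw, preprocessed_reads=preprocessed))

    frame = pd.DataFrame(columns, index=pd.Index(roster.taxon_ids,
                                                 name="taxon_id"))
    frame = pd.concat([frame, control_counts], axis=1)
    table = TaxonCountTable(frame, roster.lineages)
    records = records + control_records
    truth = GroundTruth(domination_events=truth_dom, exposed=truth_exposed,
                        skin_episode=truth_skin, qc_fate=fate)
    truth.validate_ids(sample_ids)
    return table, records, intervals, tree, truth
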