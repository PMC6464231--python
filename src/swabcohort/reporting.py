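"""Cohort-level statistics and summary tables.

Builds the study-style summary: sequencing depth and alpha diversity per
stratum (all / baseline / post-baseline / antibiotic-exposed / unexposed)
with Welch two-tailed t-tests, domination frequency tables by rank
(percent of samples and of patients), the skin-commensal table, paired
taxonomic-profile R² for validation comparisons, and protocol
completeness. No multiple-testing correction is applied; p-values are
printed to three decimals with a "<0.001" floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import QCStatus, SampleRecord
from .diversity import alpha_frame
from .events import SKIN_GENERA, DominationCall, SkinFlag
from .qc import QCReport


# ---------------------------------------------------------------------------
# elementary statistics

def welch_t(x, y) -> tuple[float, float, float]:
    """Welch unequal-variance two-tailed t-test: (t, df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("welch_t needs at least 2 observations per group")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def chi_square_2x2(table, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2×2 table: (chi2, p).

    Continuity (Yates) correction is off by default; pass
    ``correction=True`` for the corrected variant.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2) or np.any(arr < 0):
        raise ValueError("need a non-negative 2x2 table")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("zero margin in 2x2 table")
    res = stats.chi2_contingency(arr, correction=correction)
    return float(res.statistic), float(res.pvalue)


def profile_r2(profile_a, profile_b) -> float:
    """Squared Pearson correlation of two relative-abundance profiles.

    Profiles are aligned on the union of their taxa (absent = 0).
    """
    a = pd.Series(profile_a, dtype=float)
    b = pd.Series(profile_b, dtype=float)
    union = a.index.union(b.index)
    a = a.reindex(union, fill_value=0.0)
    b = b.reindex(union, fill_value=0.0)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance profile")
    r = float(stats.pearsonr(a.to_numpy(), b.to_numpy()).statistic)
    return r * r


def completeness_rate(collected: int, planned: int) -> float:
    """Protocol adherence: percent of planned samples actually collected."""
    if planned <= 0 or collected < 0 or collected > planned:
        raise ValueError("need 0 <= collected <= planned, planned > 0")
    return 100.0 * collected / planned


def format_p(p: float) -> str:
    """Three-decimal p-value string with a '<0.001' floor."""
    return "<0.001" if p < 0.001 else f"{p:.3f}"


# ---------------------------------------------------------------------------
# cohort summary

@dataclass
class CohortSummary:
    """All summary tables of one cohort run.

    ``alpha_by_stratum`` mirrors the depth/diversity table with baseline
    vs post-baseline comparison; ``alpha_by_exposure`` the
    exposed-vs-unexposed contrast; ``domination_frequencies`` one frame
    per rank; ``skin_table`` the per-genus increased/dominated/shift
    rows. ``tests`` holds every computed (statistic, df, p) keyed by
    comparison name.
    """

    n_patients: int
    alpha_by_stratum: pd.DataFrame
    alpha_by_exposure: pd.DataFrame | None
    domination_frequencies: dict[str, pd.DataFrame]
    skin_table: pd.DataFrame
    qc: QCReport
    completeness_percent: float | None = None
    tests: dict[str, tuple] = field(default_factory=dict)

    def to_report(self) -> dict:
        """JSON-serializable run report."""
        report = {
            "n_input_samples": self.qc.n_input,
            "n_retained_samples": self.qc.n_retained,
            "percent_excluded": round(self.qc.percent_excluded, 1),
            "n_patients": self.n_patients,
            "tests": {k: {"statistic": round(v[0], 4),
                          "p": format_p(v[-1])}
                      for k, v in self.tests.items()},
            "note": "p-values are uncorrected for multiple testing",
        }
        if self.completeness_percent is not None:
            report["completeness_percent"] = round(
                self.completeness_percent, 1)
        return report


def _stratum_stats(frame: pd.DataFrame, label: str) -> dict:
    out: dict = {"stratum": label, "n": len(frame)}
    for col in frame.columns:
        vals = frame[col].to_numpy(dtype=float)
        out[f"{col}_mean"] = vals.mean() if vals.size else np.nan
        out[f"{col}_sd"] = vals.std(ddof=1) if vals.size > 1 else np.nan
        out[f"{col}_min"] = vals.min() if vals.size else np.nan
        out[f"{col}_max"] = vals.max() if vals.size else np.nan
    return out


def _frequency_table(calls: Sequence[DominationCall], rank: str,
                     sample_patient: Mapping[str, str],
                     n_samples: int, n_patients: int) -> pd.DataFrame:
    rank_calls = [c for c in calls if c.rank == rank]
    rows = []
    by_taxon: dict[str, list[DominationCall]] = {}
    for c in rank_calls:
        by_taxon.setdefault(c.taxon, []).append(c)

    def row(taxon: str, taxon_calls: Sequence[DominationCall]) -> dict:
        samples = {c.sample_id for c in taxon_calls}
        pats = {sample_patient[s] for s in samples}
        return {
            "taxon": taxon,
            "n_samples": len(samples),
            "percent_samples": round(100.0 * len(samples) / n_samples, 1)
            if n_samples else 0.0,
            "n_patients": len(pats),
            "percent_patients": round(100.0 * len(pats) / n_patients, 1)
            if n_patients else 0.0,
        }

    rows.append(row("any", rank_calls))
    for taxon in sorted(by_taxon,
                        key=lambda t: (-len(by_taxon[t]), t)):
        rows.append(row(taxon, by_taxon[taxon]))
    return pd.DataFrame(rows, columns=["taxon", "n_samples",
                                       "percent_samples", "n_patients",
                                       "percent_patients"])


def _skin_rows(flags: Sequence[SkinFlag], genus_filter,
               sample_patient: Mapping[str, str],
               n_samples: int, n_patients: int, label: str) -> list[dict]:
    rows = []
    for attr, name in (("increased", "abundance >10%"),
                       ("dominated", "domination"),
                       ("shift_adjacent", "shift in adjacent sample")):
        samples = {f.sample_id for f in flags
                   if genus_filter(f.genus) and getattr(f, attr)}
        pats = {sample_patient[s] for s in samples}
        rows.append({
            "genus": label, "event": name,
            "n_samples": len(samples),
            "percent_samples": round(100.0 * len(samples) / n_samples, 1)
            if n_samples else 0.0,
            "n_patients": len(pats),
            "percent_patients": round(100.0 * len(pats) / n_patients, 1)
            if n_patients else 0.0,
        })
    return rows


def summarize_cohort(alpha_records,
                     qc_report: QCReport,
                     domination_calls: Sequence[DominationCall],
                     skin_flags: Sequence[SkinFlag],
                     records: Sequence[SampleRecord],
                     exposed: Mapping[str, bool] | None = None,
                     planned_samples: int | None = None) -> CohortSummary:
    """Aggregate one cohort run into the study-style summary tables."""
    rec_map = {r.sample_id: r for r in records if not r.is_negative_control}
    retained = [s for s, st in qc_report.statuses.items()
                if st == QCStatus.PASSED]
    missing = sorted(set(retained) - set(rec_map))
    if missing:
        raise ValueError(f"retained samples without metadata: {missing}")
    alpha = alpha_frame(alpha_records) if not isinstance(
        alpha_records, pd.DataFrame) else alpha_records
    missing = sorted(set(retained) - set(alpha.index))
    if missing:
        raise ValueError(f"retained samples without alpha records: {missing}")

    frame = alpha.loc[retained].copy()
    frame["sequences"] = [rec_map[s].preprocessed_reads for s in retained]
    frame["day"] = [rec_map[s].day for s in retained]
    metrics = ["sequences", "shannon", "inv_simpson", "faith_pd"]

    baseline = frame[frame["day"] == 0]
    post = frame[frame["day"] > 0]
    strata = [_stratum_stats(frame[metrics], "all"),
              _stratum_stats(baseline[metrics], "baseline"),
              _stratum_stats(post[metrics], "post_baseline")]

    tests: dict[str, tuple] = {}
    for metric in metrics:
        if len(baseline) >= 2 and len(post) >= 2:
            tests[f"{metric}_baseline_vs_post"] = welch_t(
                baseline[metric], post[metric])

    exposure_frame = None
    if exposed is not None:
        exp_ids = [s for s in retained if exposed.get(s, False)]
        unexp_ids = [s for s in retained if not exposed.get(s, False)]
        exposure_frame = pd.DataFrame(
            [_stratum_stats(frame.loc[unexp_ids, metrics], "unexposed"),
             _stratum_stats(frame.loc[exp_ids, metrics], "exposed")])
        for metric in metrics:
            if len(exp_ids) >= 2 and len(unexp_ids) >= 2:
                tests[f"{metric}_unexposed_vs_exposed"] = welch_t(
                    frame.loc[unexp_ids, metric], frame.loc[exp_ids, metric])

    sample_patient = {s: rec_map[s].patient_id for s in retained}
    patients = {r.patient_id for r in records if not r.is_negative_control}
    n_patients = len(patients)
    n_samples = len(retained)

    freq = {rank: _frequency_table(domination_calls, rank, sample_patient,
                                   n_samples, n_patients)
            for rank in ("family", "genus")}

    # baseline vs post-baseline domination contrasts (chi-square)
    base_ids = set(baseline.index)
    post_ids = set(post.index)
    for rank in ("family", "genus"):
        dominated = {c.sample_id for c in domination_calls if c.rank == rank}
        table = [[len(base_ids & dominated), len(base_ids - dominated)],
                 [len(post_ids & dominated), len(post_ids - dominated)]]
        arr = np.asarray(table)
        if not (np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0)):
            chi2, p = chi_square_2x2(arr)
            tests[f"any_domination_{rank}_baseline_vs_post"] = (chi2, 1.0, p)

    skin_rows = []
    for genus in SKIN_GENERA:
        skin_rows += _skin_rows(skin_flags, lambda g, genus=genus: g == genus,
                                sample_patient, n_samples, n_patients, genus)
    skin_rows += _skin_rows(skin_flags, lambda g: True, sample_patient,
                            n_samples, n_patients, "any")
    skin_table = pd.DataFrame(skin_rows)

    completeness = None
    if planned_samples is not None:
        completeness = completeness_rate(qc_report.n_input, planned_samples)

    return CohortSummary(
        n_patients=n_patients,
        alpha_by_stratum=pd.DataFrame(strata),
        alpha_by_exposure=exposure_frame,
        domination_frequencies=freq,
        skin_table=skin_table,
        qc=qc_report,
        completeness_percent=completeness,
        tests=tests,
    )
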