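# swabcohort

Analysis pipeline for longitudinal 16S rRNA gut-microbiome cohorts
sampled by rectal swab — the kind of data collected weekly from
hemato-oncology inpatients under chemotherapy and antibiotic pressure.
It is aimed at bioinformaticians who have per-sample OTU/taxon count
tables (post taxonomic profiling) and need the downstream cohort
analysis: sample QC, rarefaction, diversity, and rule-based clinical
event calls, with every step testable against a built-in synthetic
cohort simulator that carries ground-truth labels.

## What it computes

**QC cascade.** Patient samples are excluded, in order, when (1) their
raw read count is strictly below the largest negative-control read count
of their sequencing run ("failed sequencing"), (2) they hold fewer than
2,000 sequences after read preprocessing, or (3) fewer than 2,000
sequences in the OTU table after rare-taxon removal (taxa with < 0.01%
of the grand total are dropped). Survivors are rarefied to 2,000
sequences by a single seeded draw without replacement.

**Diversity.** For a sample with taxon proportions *p₁…p_S*:

- Shannon index `H = −Σ pᵢ ln pᵢ` (natural log),
- inverse Simpson `D₂ = 1 / Σ pᵢ²`,
- Faith's phylogenetic diversity: total branch length of the minimal
  subtree connecting the observed taxa and the root ("PD whole tree"
  convention),
- weighted UniFrac between samples A and B:
  `d(A,B) = Σ_b l_b |P_A(b) − P_B(b)|` over branches *b* with length
  *l_b*, where *P_X(b)* is the fraction of sample X's sequences
  descending through *b*; normalized by `Σ_b l_b (P_A(b) + P_B(b))` so
  distances lie in [0, 1]. Ordination by classical PCoA.

**Event rules.** A sample is *dominated* at a rank (family or genus)
when one taxon holds ≥ 30% of its sequences and is the unique most
abundant taxon. A sample is *antibiotic-exposed* when some course
[start, end] satisfies `start ≤ day − 3 and end ≥ day` (ongoing ≥ 3
days) or `end < day ≤ end + 2` (just terminated). The skin genera
*Corynebacterium*, *Staphylococcus* and *Streptococcus* are flagged
*increased* above 10%, *dominated* per the rule above, and *shifted*
when a domination has an adjacent same-patient sample above 10%.

**Cohort summary.** Stratum tables (all / baseline day-0 /
post-baseline / exposed / unexposed) with mean ± SD and ranges, Welch
two-tailed t-tests, uncorrected Pearson chi-square contrasts,
domination frequency tables by rank (percent of samples and of
patients), the skin-commensal table, paired-profile R² for validation
pairs, and the protocol completeness rate.

**Simulator.** `generate_cohort` draws a Dirichlet-multinomial cohort
(default 41 patients, weekly samples, ~120 taxa in realistic gut, skin
and reagent-contaminant families, log-normal read depths, per-run
negative controls with 0–298 reads) and injects antibiotic-driven
diversity loss, domination events and skin episodes — returning the
ground truth so recovery can be measured.

## Worked example

```python
import swabcohort as sc

cfg = sc.SyntheticCohortConfig(seed=1)
table, records, intervals, tree, truth = sc.generate_cohort(cfg)
report, rarefied = sc.run_qc_cascade(table, records, seed=1)
print(report.n_input, report.n_retained)          # 337 331

alpha = sc.alpha_frame(sc.alpha_table(rarefied, tree))
flags = sc.exposure_flags(records, intervals)
exposed = [s for s in report.retained_ids() if flags[s]]
unexposed = [s for s in report.retained_ids() if not flags[s]]
t, df, p = sc.welch_t(alpha.loc[unexposed, "shannon"],
                      alpha.loc[exposed, "shannon"])
```

This cohort yields 337 patient samples of which 331 pass QC (1 failed
sequencing, 4 below 2,000 preprocessed reads, 1 below 2,000 in the OTU
table). Mean Shannon diversity is 3.17 in the 269 unexposed retained
samples versus 2.88 in the 62 antibiotic-exposed ones (Welch t = 2.92,
p = 0.004) — the expected antibiotic-driven diversity loss. Genus-level
domination calling finds 78 dominated samples, most frequently by
*Enterococcus* (38 samples), matching the injected event profile.

The same pipeline runs from the shell:

```
swabcohort simulate --out sim --seed 1
swabcohort qc --table sim/counts.tsv --metadata sim/metadata.tsv \
    --seed 1 --out qc
swabcohort diversity --table qc/rarefied_table.tsv --tree sim/tree.nwk \
    --out alpha.tsv
swabcohort classify --table qc/rarefied_table.tsv \
    --metadata sim/metadata.tsv --exposures sim/exposures.tsv --out cls
swabcohort summarize --alpha alpha.tsv --qc-report qc/qc_report.tsv \
    --dominations cls/dominations.tsv --skin cls/skin_flags.tsv \
    --metadata sim/metadata.tsv --exposure-labels cls/exposure_labels.tsv \
    --out summary
```

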