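# Methods

## Scope and data model

The package operates strictly downstream of taxonomic profiling: its
inputs are a taxa × samples integer count table with rank-prefixed
lineages (`k__;p__;c__;o__;f__;g__`, SILVA/QIIME-like), per-sample
metadata (patient, day since baseline, run, negative-control flag, raw
and preprocessed read counts), antibiotic administration intervals in
study days, and a rooted newick phylogeny whose leaves are the table's
taxon ids. Read-level processing (trimming, merging, chimera removal,
OTU picking) is out of scope. Days are integers; the sampling design is
weekly, so sub-day resolution would be spurious precision. Counts stay
integers end to end — rarefied tables are integer by construction.

Unassigned ranks are written as an empty value after the prefix
(`g__`) and aggregate as a distinct `Unclassified <parent>` bin keyed by
the nearest classified ancestor, so unclassified-genus reads of
different families are never pooled.

## QC cascade

Five stages in a fixed order; a sample failing several criteria is
reported under the earliest stage, so exclusion categories are mutually
exclusive and `n_input = n_retained + Σ exclusions` always holds.

1. **Failed sequencing.** A patient sample whose raw read count is
   *strictly below the maximum* negative-control read count of its run
   is indistinguishable from a blank. Reading "below the controls" as
   the run maximum is the conservative choice — it excludes anything a
   blank could explain; the comparison function is isolated so a
   min/mean reading is a one-line change. A run containing patient
   samples but no control is an error naming the run.
2. **Preprocessed-read filter.** Strictly fewer than 2,000 sequences
   after quality/chimera filtering (metadata column).
3. **Rare-taxon filter.** Taxa with a grand-total count strictly below
   0.01% of the table's grand total are dropped. The grand total is
   computed once, over all samples surviving stages 1–2 (not per run).
4. **OTU-table read filter.** Column sums strictly below 2,000 after
   stage 3.
5. **Rarefaction.** One seeded multivariate-hypergeometric draw (urn
   subsampling without replacement) to 2,000 sequences per surviving
   sample. A single draw rather than an average of draws: averaging
   would produce non-integer counts and break downstream integer
   invariants.

Whether the rare-taxon filter precedes or follows the sample filters is
a design choice here (it sits between the two read filters, so the
OTU-table filter sees the filtered table); the cascade is deterministic
for a fixed seed either way.

Re-running the cascade on its own output is a no-op in practice and in
the test suite's conditions. The one theoretical exception: a taxon
sitting exactly at the 0.01% boundary can fall below it after
rarefaction re-scales the grand total. The simulator's communities keep
taxa well away from that boundary, so the idempotence test is exact
there; on real data a boundary taxon could flip.

## Diversity

All metrics are computed from first principles on rarefied counts;
passing an unrarefied table (unequal column sums) is refused unless
explicitly overridden, because unequal effort biases every metric.

- **Shannon** uses the natural log. With ~100-taxon communities this
  puts typical values in the 0–4.5 range.
- **Faith's PD** is root-inclusive ("PD whole tree"): the branch length
  of the minimal subtree connecting the observed taxa *and the root*.
  For a single observed taxon PD is its root path length, not zero.
- **Weighted UniFrac** is implemented branch-wise:
  `Σ_b l_b |P_A(b) − P_B(b)|` with `P_X(b)` the fraction of X's
  sequences descending through branch *b*. The default is the
  normalized variant (divide by `Σ_b l_b (P_A(b) + P_B(b))`), which is
  scale-free and bounded in [0, 1]; the raw variant (a weighted L1
  metric that satisfies the triangle inequality exactly) is a flag
  away. Both agree with scikit-bio's implementation to 1e-9 in the
  cross-check tests.
- **PCoA** is classical metric scaling: double-center the squared
  distance matrix, eigendecompose (the Gram matrix is symmetrized
  before `eigh` to suppress round-off asymmetry), order axes by
  eigenvalue. Negative eigenvalues are reported, not hidden; requesting
  more axes than there are positive eigenvalues returns fewer with a
  warning. Explained fractions are relative to the positive part of the
  spectrum.

## Event rules

- **Domination**: proportion ≥ 0.30 (inclusive, "at least") *and*
  strictly greater than every other taxon at that rank. A tie at the
  maximum yields no call and a log line — requiring a unique most
  abundant taxon avoids double-counting a sample in frequency tables.
- **Increased skin-commensal abundance**: proportion > 0.10 (strict,
  "more than"). The inclusive/strict asymmetry between the two
  thresholds is deliberate and mirrors their verbal definitions.
- **Exposure**: exposed iff some interval satisfies
  `start ≤ day − 3 ∧ end ≥ day`, or `end < day ≤ end + 2`. Intervals of
  different agents are tested independently by default; a back-to-back
  agent switch can therefore read as unexposed on day 1–2 of the new
  course even though the patient was continuously treated. A
  `merge_intervals` flag merges overlapping/abutting courses first.
  Consequently the labeling is *not* invariant to splitting one course
  into abutting sub-intervals unless merging is enabled — a known
  limitation, not a bug.
- **Shift adjacency** uses the immediately preceding/following
  *retained* sample of the same patient in day order, regardless of the
  calendar gap between them; QC-excluded samples do not break or
  provide adjacency. First/last samples have a single neighbor.

All rules operate on compositional (relative) abundances of rarefied
counts and say nothing about absolute bacterial load.

## Statistics

- **Welch's t** (unequal variance, Welch–Satterthwaite df, two-tailed)
  is the default group comparison — robust when strata sizes are
  as lopsided as exposed vs unexposed cohorts typically are. Backed by
  `scipy.stats.ttest_ind(equal_var=False)`; tests pin it to the
  explicit textbook formula to 1e-9.
- **Pearson chi-square without continuity correction** for 2×2
  frequency contrasts (`correction=True` available). Doubling all cells
  exactly doubles the statistic, which the tests use as a scale check.
- **Profile R²** is the squared Pearson correlation of two
  relative-abundance profiles aligned on the union of their taxa
  (absent = 0), intended at family level for swab-vs-stool style
  validation pairs; the rank is a flag.
- p-values are printed to three decimals with a `<0.001` floor. No
  multiple-testing correction is applied; the report footer says so.
- Completeness rate = 100 × collected / planned, collected ≤ planned.

## The synthetic cohort

### What it emulates

A 41-patient cohort sampled weekly (1–30 samples per patient; sample
counts 1 + truncated geometric, mean ≈ 10), five sequencing runs with
1–3 negative controls each (0–298 raw reads, sparse reagent-contaminant
profiles: Pseudomonadaceae, Comamonadaceae, Methylobacteriaceae),
log-normal read depths (log-mean 11.0, log-sd 0.7 → mean ~76k
sequences/sample), and ~120 taxa partitioned into realistic gut
families (Enterococcaceae, Lachnospiraceae, Ruminococcaceae,
Prevotellaceae, Bacteroidaceae, Enterobacteriaceae, …), the three skin
genera, and the contaminant pool. Re-admission gaps appear as
multi-week holes with probability 0.1 per step.

Community model: per patient a baseline composition is drawn from a
symmetric Dirichlet (α = 0.5); each sample re-draws from a Dirichlet
centered on it with concentration κ = 60 — enough within-patient noise
to be realistic while keeping injected events recoverable. Antibiotic
exposure multiplies the concentrations of all taxa outside a random
per-patient surviving subset (fraction 0.5) by the shrink factor
(default 0.1) and renormalizes; this mechanically lowers Shannon and PD
in exposed samples, and setting the factor to 1.0 removes the mechanism
entirely (the null the tests exploit). Domination events are injected
per post-baseline sample with probability 0.25 by forcing one focal
taxon (an *Enterococcus* OTU half the time, otherwise a random
non-skin, non-contaminant OTU) to a relative abundance drawn from
[0.35, 0.9] *after* the within-sample noise — so misses downstream can
only come from counting noise at the 2,000-read rarefaction depth,
where a 0.35 event sits ~4.7 SD above the 0.30 threshold. Skin episodes
raise one skin genus to [0.12, 0.28] for 1–3 consecutive samples in 30%
of patients, on samples without an injected domination.

Antibiotic courses: every patient except one random untreated patient
receives 1 + Poisson(1.5) courses of 4–21 days at uniform starts; the
generator computes each sample's exposure flag with the same ≥3-day /
≤2-day arithmetic the labeler implements, so ground-truth labels and
interval files are consistent by construction.

QC fates: 1% of samples are destined to fail sequencing (raw reads
drawn uniformly below their run's control maximum; only runs with a
control maximum ≥ 10 are used so the rule is actually exercisable), 1%
to fall under 2,000 preprocessed reads, 0.5% under 2,000 OTU-table
reads. For fixture construction the config accepts exact planting
counts and an exact cohort-wide sample total instead. The read-depth
log-normal is truncated below (preprocessed ≥ 2,100) for
intended-to-pass samples so planted fixtures exclude exactly the
planted samples.

The phylogeny is a random coalescent-style binary tree with
exponential(1) branch lengths in which family mates form clades —
enough phylogenetic signal for PD and UniFrac to be non-trivial.

### What it does not emulate

No sequencing-error or chimera structure, no PCR/primer bias, no
contaminant leakage into patient samples, no taxon-assignment
uncertainty, no temporal autocorrelation beyond the shared patient
baseline (consecutive samples are conditionally independent draws), no
abundance–depth coupling, and no fitting to any real accession. Tests
passing on this simulator therefore demonstrate that the *rules and
metrics* are implemented correctly and recover known structure under
realistic noise — not that the pipeline's clinical conclusions transfer
to any particular real dataset.

## Numerical and degenerate-input choices

- Rarefaction of a sample whose total equals the depth returns it
  unchanged; totals below depth are a caller error (the cascade
  excludes such samples beforehand).
- All-zero count vectors are rejected by every alpha metric; empty
  samples by UniFrac.
- Proportion ties in domination calling are resolved to "no call", and
  the tie is logged at INFO level.
- Distance matrices are validated symmetric to 1e-12 with a zero
  diagonal; the PCoA eigen-cutoff for "positive" eigenvalues is
  max(1e-12, 1e-10 · |λ|max).
- Randomness: every generator routine takes one `numpy` seed or
  `Generator`; a cohort is byte-identical across runs for a fixed seed.

## Problem sizes in the test suite

The suite runs default-scale cohorts (41 patients, ~350–500 samples)
where cohort structure matters, a 10-seed sweep for parameter recovery,
1,000 random profiles for rule-engine equivalence, 100 random
triples/instances for metric properties, and 10,000 draws for the
rarefaction goodness-of-fit — sizes chosen so each check is
statistically meaningful while the whole suite stays fast enough to run
on every commit.

## Known limitations

- Exposure labeling without `merge_intervals` is sensitive to how
  courses are recorded (see above).
- Cascade idempotence is exact only away from the 0.01% rare-taxon
  boundary.
- The "percentage of patients" denominators use all patients
  contributing samples, so columns summed across taxa can exceed 100% —
  intended, since a patient can be dominated by different taxa over
  time.
- Weighted UniFrac's normalized variant is not a metric (the raw one
  is); ordination of either is fine, but triangle-inequality-dependent
  algorithms should use the raw variant.
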