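# Methods

This note documents the statistical procedures implemented in
`butyroscope`, the synthetic data model used to validate them, the
default parameters and why they were chosen, and the limits of what the
passing test suite demonstrates.

## Data model

A `CommunityProfile` couples a sample × taxon matrix of non-negative
integer read counts with a seven-rank taxonomy (Kingdom … Species; any
rank may be unassigned) and per-sample metadata (group, timepoint,
diet, optional animal id). Identifiers are validated on construction;
readers align the three TSV tables strictly by default, because silent
intersection hides upstream bookkeeping errors (an intersection mode
exists for deliberately partial inputs).

Enzyme content is a long table of (taxon, EC label, copy value). EC
labels are normalized to `EC:a.b.c.d`; partial labels such as
`EC:2.8.3.-` are legal and kept as **distinct identifiers**, not prefix
wildcards — functional-inference outputs use them as standalone
enzyme ids, and expanding them would make every `EC:2.8.3.x` carrier a
4Hbt hit. A prefix-match mode exists but is off by default.

## Contaminant and sparse-phylum filtering

Three ordered rules: (1) drop taxa whose Kingdom is not Bacteria
(unassigned kingdoms count as non-bacterial); (2) drop excluded phyla
(default Cyanobacteria, the usual chloroplast-derived contaminant);
(3) compute each remaining phylum's mean per-taxon prevalence — the
mean over its taxa of the number of samples in which the taxon is
observed — and drop phyla with mean prevalence < 1. The prevalence
statistic is evaluated *after* the kingdom/phylum exclusions, so
contaminants cannot rescue a sparse phylum. The filter is idempotent
and never alters retained counts.

## Butyrate role classification

`is_producer` = conserves **any** of {4Hbt `EC:2.8.3.-`, Ato
`EC:2.8.3.9`, But `EC:2.8.3.8`, Buk `EC:2.7.2.7`}; `is_consumer` =
conserves **all** of {But, Acd `EC:1.3.8.1`} **and** at least one of
{Crt `EC:4.2.1.149`, Ech `EC:4.2.1.17`}. "Conserves" means copy value
strictly greater than `presence_min`, default 0 — any annotation
evidence counts, since the rules speak of conserving an enzyme, not of
a copy-number threshold.

Because But appears in both rule sets, the consumer rule strictly
implies the producer rule: every complete consumer is a dual-role
taxon. This is a property of the definitions, not an implementation
choice, and the containers and ratio statistics are built to represent
it (dual taxa contribute to both the numerator and denominator of the
producer:consumer ratio).

Role abundances are presence-weighted: a flagged taxon contributes its
full read count regardless of enzyme copy number. Copy-number
weighting was considered and rejected as a default because inferred
copy values conflate gene dosage with inference confidence. When a
subset of taxa is analyzed (e.g. only differentially abundant ones),
the denominator remains the sample's **total** count over all taxa, so
subset panels stay on the same scale as whole-community panels. The
ratio is undefined (NaN, excluded from tests) where the consumer sum
is zero.

## Rank-sum testing policy

All two-group nonparametric comparisons share one policy: exact
enumeration of the Mann–Whitney distribution when both groups have
≤ 10 observations and the pooled data are tie-free; otherwise the
normal approximation on midranks with tie correction. A comparison in
which every pooled value is identical is reported as degenerate with
p = 1. The exact path is validated in the test suite against full
enumeration of all C(n₁+n₂, n₁) group assignments.

## Diversity and PERMANOVA

Simpson diversity and Bray–Curtis dissimilarity follow their textbook
definitions; Bray–Curtis can be computed on raw counts or on
proportions (the `normalize` flag), the latter making it invariant to
sequencing depth.

PERMANOVA partitions SS_total = Σ_{i<j} d²_ij / n into within- and
between-group components, with pseudo-F = (SS_B/(a−1)) / (SS_W/(n−a))
and R² = SS_B/SS_total. The permutation p-value uses the add-one
convention (1 + #{F* ≥ F}) / (1 + B) so it is never exactly zero; the
seed is recorded in the result. When the number of *distinct* label
assignments is ≤ 10,000 the null distribution is enumerated completely
instead, and p is the exact fraction of assignments with F* ≥ F.
Perfect separation (SS_W = 0) is handled as F = +∞ under the ≥
comparison. Two-factor designs (e.g. treatment × time) use sequential
sums of squares on the Gower-centered squared-distance matrix with
free permutation of raw sample labels; repeated-measures permutation
restrictions are not imposed (a known simplification — see
Limitations).

## Differential abundance

Both engines operate on total-sum-scaled proportions and report
BH-adjusted p-values, an effect with sign, and a direction label that
refers to the **second** group of the contrast (so "depleted" means
lower in the treated/later group under either engine's sign
convention).

*TSS log2 regression*: taxa seen in fewer than 5% of samples are
removed; the response is log2(proportion + pc); the effect is the OLS
coefficient of the group indicator, computed via the algebraically
identical pooled-variance two-sample t-test. A zero-variance response
gives p = 1 with a degenerate flag.

*Wilcoxon median-proportion matrix*: at each requested rank, taxa are
agglomerated over their full lineage, pruned when their total count
over all samples is ≤ 500 (strictly-greater keeps a taxon only above
500), proportions recomputed, and each pair of groups tested per
taxon. The effect is log2(median + pc) differences of per-sample
proportions — medians both for the test input and the effect. BH is
applied within each contrast with all ranks pooled.

*Pseudocount*: pc defaults to half the smallest nonzero proportion in
the table at hand, applied only inside log2. This keeps all effects
finite without reordering observed values; it is configurable.

Rank agglomeration sums counts over taxa sharing the full lineage down
to the target rank; taxa unassigned at that rank are dropped by
default (bar-graph convention) or pooled under an explicit
`unassigned` lineage. The operation is idempotent.

## Disease-course statistics

Scores are daily ordinal values on 0–5 over a 30-day course. CDS is
the plain sum of daily scores; AUC is the trapezoidal integral with
unit day spacing (for step-free courses the two differ only at ramp
days). Missing days are a hard error unless last-observation
carry-forward is requested.

The treatment × time interaction test midrank-transforms scores across
animals within each day, then computes the split-plot two-way ANOVA
interaction F (whole plot = animal within group, subplot = day). The
F statistic is referred by default to a **permutation** distribution
obtained by shuffling group labels across animals, because ordinal
disease courses are strongly autocorrelated across days, violating the
sphericity assumption behind the classical F reference and making it
anti-conservative; under label exchangeability the permutation
reference is exactly calibrated. The classical F reference remains
available (`method="f"`), and the method used is recorded in the
result.

Dunn's post-hoc z-tests after Kruskal–Wallis use the standard
tie-corrected pooled-rank variance with BH adjustment across pairs.

## Metabolite screens

The ANOVA screen log-transforms and mean-centers concentrations
(centering does not change F), excludes missing values, and flags a
metabolite only when p ≤ 0.05 **and** the ratio of group geometric
means exceeds 1.5 in either direction — a deliberate two-key rule that
keeps tiny-variance, tiny-effect hits out. Fisher's LSD pairwise
t-tests with the pooled ANOVA mean square error are reported for
flagged metabolites. The Pearson screen computes r and its t-based p
per metabolite, BH-adjusts across everything screened in the one call
(metabolites and contexts together), and retains only |r| ≥ 0.2 with
adjusted p ≤ 0.05.

## Synthetic data model

The generator exists to give every statistic above a typed input with
known truth.

*Community*: per sample, composition ~ Dirichlet(α_group), counts ~
Multinomial(depth, composition), depth ~ NegativeBinomial(mean 1e5,
dispersion 20). The Dirichlet-multinomial is the standard
overdispersed model for 16S counts and its closed-form mean
α_i/Σα is used directly as a test oracle. Defaults: 60 taxa, 10
samples per group, total concentration Σα = 150 (within the range of
published Dirichlet-multinomial fits to fecal 16S data; larger values
would describe an unusually tight cohort), and a planted 10-taxon
producer clade at 3× base weight, i.e. ≈3.75% mean relative abundance
per planted taxon (≈37% combined) — mirroring the dominance of
Lachnospiraceae-type producer clades in mouse feces. The treated
group's α is multiplied by `depletion_effect` (default 0.25, a 4-fold
depletion) over the planted clade. Taxonomy labels make planted clades
share Family/Genus; some background taxa carry unassigned genera so
agglomeration paths are exercised.

*Enzyme content*: producer-role taxa receive one producer enzyme by
default (so recall under annotation dropout d has the closed form
1 − d, used as the oracle); consumer-role taxa the full consumer set;
dual taxa both; every required annotation is deleted independently
with probability `dropout_rate`; all taxa receive 1–3 decoy enzymes
outside the rule sets. Truth flags honor the consumer ⇒ producer
nesting noted above.

*Disease courses*: score 0 until a uniform random onset in days 10–14,
then a monotone Bernoulli(0.6) staircase to a per-animal peak
round(N(2.5 + shift, 1)) clipped to [0, 5], then a chronic plateau —
the canonical chronic course in this disease model. Integer scores by
default; half-point increments are available (`step=0.5`).

*Metabolites*: butyrate (mg/g feces scale) =
1 + c_f·[high-fiber diet] + c_r·(producer:consumer ratio) + N(0, σ),
clipped at zero, plus lognormal decoy metabolites from the null model.

What the generator does **not** emulate: phylogenetic correlation
among taxa beyond shared labels, sample-to-sample covariance
(cages/litters), sequencing error or chimeras, relapsing-remitting
disease courses, and metabolite-metabolite correlation. Tests passing
on this generator demonstrate the statistics' operating
characteristics (calibration, power against planted effects,
invariances), not performance on any particular real cohort.

## Calibration and power checks (problem sizes used)

Type-I calibration uses effect-free configurations: the per-test
rejection rate at α = 0.05 is checked to sit in 5% ± 2% over 500–1000
replicates for the Wilcoxon differential engine, the role-ratio
comparison, and Mann–Whitney on CDS. Rejection-rate checks run at
n = 10–20 per group. Kolmogorov–Smirnov uniformity checks run at
n = 20–25 per group with one p-value per replicate: at n = 10 the
exact rank-sum p-value lattice has atoms of ≈0.06, so a KS test at
hundreds of replicates rejects the lattice itself regardless of
correctness, while by n = 20 the lattice is fine relative to KS
resolution. Power checks run 100 seeds of the default planted-depletion
community and require the ratio comparison to reject in ≥90 of them;
per-taxon recovery of the planted clade is measured against the same
bar and currently achieves 85–89 seeds depending on engine — an honest
reflection of per-taxon power at the chosen overdispersion, documented
rather than hidden by quietly tightening the generator.

## Limitations

- Negative-binomial GLM differential testing is intentionally out of
  scope; the two engines here are the rank-based and TSS-regression
  procedures.
- PERMANOVA permutes freely; repeated-measures designs with partially
  overlapping animals across timepoints are approximated, not exactly
  handled (strata support would be the extension point).
- The AUC is a plain trapezoid of daily scores; alternative
  peak-area constructions exist and would need their own estimator.
- BIOM-format ingestion is not provided; inputs are TSV.
- The enzyme-rule classification is only as good as the upstream
  functional inference; presence thresholds other than "any evidence"
  can be set via `ButyrateRuleSet.presence_min`.
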