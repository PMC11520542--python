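# butyroscope

Analysis toolkit for asking a focused question of gut microbiome 16S
count data: **is the community's capacity to produce butyrate being
eroded, and does that matter for host disease?**

Short-chain fatty acids (SCFAs), and butyrate in particular, are
immunomodulatory products of microbial fiber fermentation, and their
depletion is a recurring signature in neuroinflammatory disease. Given
a sample × taxon count table with taxonomy, per-taxon enzyme content
(e.g. inferred metagenomes in the stratified-contribution layout), and
per-animal clinical scores, `butyroscope` provides the downstream
statistics for that question, plus a synthetic-data generator with
known ground truth so every stage can be validated end to end.

## What it computes

**Enzyme-rule role classification.** A taxon is a *butyrate producer*
if it conserves any terminal enzyme of a butyrate-producing pathway:

- 4Hbt, butyryl-CoA:4-hydroxybutyrate CoA transferase — `EC:2.8.3.-`
- Ato, butyryl-CoA:acetoacetate CoA transferase — `EC:2.8.3.9`
- But, butyryl-CoA:acetate CoA transferase — `EC:2.8.3.8`
- Buk, butyrate kinase — `EC:2.7.2.7`

and a *butyrate consumer* if it conserves **each** of But (`EC:2.8.3.8`)
and Acd, acyl-CoA dehydrogenase (`EC:1.3.8.1`), **and** at least one of
Crt (`EC:4.2.1.149`) / Ech (`EC:4.2.1.17`). Dual roles are expected —
every complete consumer also satisfies the producer rule through But.
Per sample, the summed relative abundance of producers P_s and
consumers C_s and their ratio P_s/C_s summarize net butyrate potential;
groups are compared by two-sided Wilcoxon rank-sum tests (exact when
both n ≤ 10 and tie-free).

**Diversity.** Simpson index 1 − Σ p_i²; Bray–Curtis dissimilarity
d(x,y) = Σ|x_i−y_i| / Σ(x_i+y_i); one- and two-factor PERMANOVA built
from first principles (SS partition on squared dissimilarities,
pseudo-F, R², permutation p with the add-one convention, exhaustive
enumeration when the label-assignment space is small).

**Differential abundance** on total-sum-scaled proportions, after rank
agglomeration:

- per-taxon OLS of log2(proportion + pc) on a group indicator with a
  minimum-prevalence filter (default 0.05); effect = log2 fold-change;
- the heat-tree matrix procedure: prune taxa with total count ≤ 500,
  per-sample proportions, per-taxon two-sided Wilcoxon rank-sum for
  every group contrast, effect = difference of log2 median proportions;

both with Benjamini–Hochberg adjustment.

**Disease-course statistics** for daily ordinal 0–5 clinical scores
over a 30-day course: cumulative disease score (CDS = Σ daily scores),
trapezoidal AUC, Mann–Whitney and Kruskal–Wallis + Dunn group tests,
and a treatment × time interaction test on within-day ranks with a
permutation reference.

**Metabolite screens**: one-way ANOVA on log concentrations with a
|fold-change| > 1.5 floor and Fisher's LSD post-hoc tests, and a
Pearson screen against disease severity retaining metabolites with
|r| ≥ 0.2 at BH-adjusted p ≤ 0.05.

## Worked example

Run the full seeded synthetic study — a 60-taxon, 10-samples-per-group
community in which a 10-taxon producer clade is depleted 4-fold in the
treated group, with matching enzyme content, disease courses and
metabolites:

```sh
butyroscope pipeline --seed 1 --out results/demo
```

which prints (among other fields):

```json
{
  "mean_ratio_control": 4.466373166577596,
  "mean_ratio_treated": 1.679256408598219,
  "ratio_p_value": 1.082508822446903e-05,
  "permanova_r_squared": 0.29567531153315757,
  "permanova_p_value": 0.001,
  "n_tss_significant": 14,
  "n_wilcoxon_significant": 13,
  "planted_taxa_recovered": 9,
  "n_planted": 10,
  "mean_cds_control": 53.0,
  "mean_cds_treated": 66.0,
  "cds_p_value": 0.05354193923094535,
  "friedman_interaction_p": 0.071
}
```

Reading: the planted depletion drives the producer:consumer ratio from
≈4.5 down to ≈1.7 (Wilcoxon p ≈ 1e−5), microbiome composition separates
by group (PERMANOVA R² ≈ 0.30, p = 0.001), the differential engines
flag 13–14 taxa of which 9 of the 10 planted producers are recovered
with direction "depleted", and the treated animals accumulate a higher
cumulative disease score (66 vs 53). All result tables (role
abundances, distance matrix, per-taxon tests, course summaries,
screens) are written as TSV under `results/demo/`; two runs at the same
seed are byte-identical.

The same steps are available piecemeal (`butyroscope simulate|filter|
butyrate|diversity|diff|disease|screen ...`) and as library functions
(`simulate_community`, `classify_butyrate_roles`, `role_abundances`,
`permanova`, `wilcoxon_differential`, ...).

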