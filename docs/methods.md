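# Methods

## Model and procedure

`syllogist` treats cell-type detection in bulk transcriptomes as a gene-set
enrichment problem rather than a deconvolution problem. Three ingredients:

1. **Signatures.** A reference atlas (gene × lineage matrix, technical
   replicates averaged by arithmetic mean) yields, per gene, the relative
   expression vector p across lineages and the entropy-based specificity
   index S = H − log₂ p_l. S is Schug's Q statistic: it is minimized (S = 0)
   for a gene expressed in exactly one lineage and grows with promiscuity
   (uniform expression gives S = 2 log₂ N). Each lineage's signature is the
   m = 80 genes with the smallest S. A gene silent in a lineage has
   S = +∞ there and can never enter that lineage's signature; a gene with
   zero expression in every lineage has undefined relative expression and
   is excluded from candidacy altogether.

2. **Scoring.** Per query sample, genes above the expression threshold form
   the expressed set E. Each signature's overlap k_obs with E is compared
   with the mean overlap k̄_null of B = 1000 random m-gene lists drawn
   uniformly without replacement from the gene universe (by default the
   reference atlas gene list). A two-sided Fisher's exact test on
   [[k_obs, m−k_obs], [k̄_null rounded, m−rounded]] gives p and the sample
   odds ratio. Odds ratios are relative abundance proxies: they support
   intersample comparison of one lineage, not composition estimates.

3. **Spike-in limit of detection.** A reference profile is mixed linearly
   into background samples at fraction f after both are renormalized to a
   common total T = 10⁶, interpreting f as an RNA-mass fraction (equal
   per-cell RNA content assumed; whether the original experiment meant
   mass or cell fraction is not derivable, so mass fraction is the
   documented choice). Spiked and unspiked cohorts are scored with
   identical settings and per-sample seeds, and a two-tailed paired
   Student's t-test on the target lineage's odds ratios gives the
   per-fraction detection p-value. At f = 0 the paired differences are
   identically zero and p is defined as 1.

## Design choices where the design was open

- **Ranking direction.** "Top genes by specificity index" is implemented as
  *most specific first* (ascending S), since the Q statistic's semantics
  make small values specific; selecting the literal maximum would pick the
  least specific genes. The direction is exposed as
  `rank_direction` ("ascending" default, "descending" available).
- **Tie-breaking.** Top-m selection sorts by (S ascending, expression in
  the lineage descending, gene id lexicographic), stable — identical
  atlases produce byte-identical signature files on any platform.
- **Expression threshold.** No universal threshold exists across platforms,
  so it is a required, recorded parameter: absolute mode (value > t,
  default t = 1, suited to TPM-like data) and quantile mode (value above
  the per-sample q-quantile, q = 0.5 recommended for intensity-like data,
  including the synthetic generator's output). The threshold and mode are
  embedded in all result metadata.
- **Null integerization.** Fisher's test needs integer counts; k̄_null is
  rounded half up for the table while the real-valued mean is reported
  alongside. One null model is built per sample (it depends on that
  sample's expressed set) and shared across lineages.
- **Odds ratio.** Sample (cross-product) odds ratio, with the
  Haldane–Anscombe +0.5 correction on all cells when any cell is zero.
  This differs from the conditional-MLE odds ratio some libraries return;
  the two-sided p-value is the standard sum of hypergeometric
  probabilities ≤ P(observed table).
- **Normalization cohort.** Normalized odds ratios are min-max per lineage
  across the samples scored in one invocation; a degenerate lineage
  (max = min) maps to 0 for all samples. Scores are therefore only
  comparable within one scored cohort.
- **Test variants.** Group comparisons default to the pooled-variance
  Student's t (Welch behind a flag) with BH adjustment across lineages;
  null drawing is per sample with seeds spawned deterministically from the
  run seed, so reruns are byte-identical.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| m (`signature_size`) | 80 | marker genes per lineage |
| B (`null_lists`) | 1000 | random lists per null model |
| t (`threshold`, `threshold_mode`) | 1.0 absolute / 0.5 quantile | expressed-gene cut |
| `universe` | atlas | gene list the null draws from |
| `alpha` | 0.05 | significance level for the detection limit |
| T (`total`) | 10⁶ | common normalization total for spike-in mixing |
| `seed` | 42 | master seed; all draws derive from it |

## The synthetic data generator

The generator emulates the *shape* of a curated expression atlas: 6
lineages × 5000 genes by default, log-normal baseline expression
(meanlog 3, sdlog 1, right-skewed like intensity data), 120 planted marker
genes per lineage at 20-fold baseline in their lineage only, 3 technical
replicates with multiplicative log-normal noise (σ = 0.3). Query cohorts
are convex mixtures of the noiseless lineage means normalized to a
sequencing-depth total, with mean-one multiplicative noise applied once
per sample so the planted weights are exact in expectation.

It deliberately does **not** model sequencing counts, gene length or GC
bias, dropout, batch effects, or correlated co-expression modules.
Passing tests therefore demonstrate that the estimator recovers planted
signal under clean mixing assumptions — they do not certify performance
on real tissue, where marker bleed-through between related lineages and
platform effects are the dominant error sources.

Test and validation problem sizes are scaled to the method's behaviour,
not the original cohorts: planted-signal recovery uses 100 seeded runs of
5-sample cohorts, and the spike-in power check uses 50 background samples
with 10 seeds over the fraction grid {0, 0.001, 0.005, 0.01, 0.05}.

## Numerical conventions

- 0·log₂ 0 := 0 in the entropy sum; probability vectors are validated to
  sum to 1 within 1e−9.
- Two-sided Fisher tail sums include tables whose probability is within a
  1 + 1e−7 relative factor of the observed table's, guarding against
  floating-point exclusion of equally extreme tables; when the whole
  support qualifies, p is exactly 1.
- Degenerate t-tests (zero variance): t = 0, p = 1 when the means agree,
  p = 0 otherwise.
- Negative input expression is floored at 0 on ingest; duplicate gene rows
  are collapsed by mean with a warning; duplicate sample ids are an error.

## Known limitations

- Enrichment scores are not proportions; they cannot be compared across
  lineages within one sample except through the null-calibrated p-values,
  and normalized scores are not comparable across separately scored
  cohorts.
- A signature saturated in every sample (all markers expressed everywhere,
  e.g. with a permissive threshold) is blind to spike-in: the detection
  limit is then undefined, which the spike-in machinery reports as "not
  reached" rather than an error.
- Benjamini–Hochberg adjusted p-values are not idempotent (re-adjusting
  adjusted values inflates them); adjust once per comparison family.
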