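# Methods

This note records the models, numerical conventions and design choices
behind `evbal`, and what the synthetic-data generator does and does not
emulate.

## Data model

The central container is a dense proteins × samples iBAQ matrix with
explicit zeros for "not identified in that sample" — never NaN.
Identification is `value > 0` on the raw matrix, so detection-based
statistics (unique-protein counts) are invariant to any monotone transform
of the intensities and are always computed on the unnormalized matrix.
Isoform rows carry their gene symbol; gene-level operations collapse by the
per-sample maximum by default (the dominant isoform's iBAQ dominates the
gene signal), with summation available.

## Preprocessing

Three strategies, applied in order: contaminant/reverse removal →
`log2(x+1)` → quantile normalization → Gaussian abundance filtering.

*Quantile normalization* operates on the full dense matrix: all cells are
ranked, zeros included, and each column's values are replaced by the
across-column mean of the sorted columns at their rank.  Tied values
within a column receive the mean of the reference over their tied ranks —
the convention of the dominant microarray implementation.  With no ties
the operation is exactly idempotent and all columns share one sorted value
multiset; with heavy ties (e.g. many zeros of unequal counts per column)
idempotence and zero-pattern preservation hold only approximately, which
is why detection-based statistics read the raw matrix instead.  Note that
rank-based normalization can only transmit effects expressible as rank
shifts: a one-sided abundance shift concentrated in the extreme upper tail
is partially absorbed into the reference (an intrinsic property of the
method, visible in the generator calibration below).

*Gaussian abundance filtering* scans a grid of candidate minimum-abundance
thresholds, zeroes values at or below each candidate, and scores the
pooled retained nonzero values for normality.  The default score is the
negated Anderson–Darling statistic (computed directly from the normal CDF
with estimated mean/sd; Shapiro–Wilk available), with subsampling to
≤ 5000 points under a fixed seed for speed.  Zeros never enter normality
scoring — they encode missingness, not abundance.  When several thresholds
leave identical retained sets (a plateau beyond the filtered component),
the smallest scoring maximum is returned.

## Differential expression

Per protein, ordinary least squares of log2(x+1) intensity on intercept +
cancer status + treatment-coded covariate dummies (gender, smoking by
default; unused levels dropped; "NA"/"unknown" kept as explicit levels so
no sample is discarded).  Zeros are data, not missing values — matching
the transformation the intensities were given.  Empirical-Bayes moderation
follows the standard formulas: residual variances are modeled as scaled
inverse-χ², the prior (d₀, s₀²) fitted by method of moments on log
variances (trigamma inversion by Newton iteration; infinite d₀ with the
arithmetic-mean scale when the spread of log variances does not exceed
chi-square sampling noise).  The moderated t uses the shrunken variance
and d_g + d₀ degrees of freedom; with d₀ forced to 0 it reduces exactly to
the OLS t.  Agreement with the Bioconductor reference implementation is
asserted in the test suite to 1e-8 on a shared toy dataset.  Proteins
below a minimum total detection count (default 3) are flagged and excluded
from the prior fit but still reported.  No intensity-trend or robust prior
options are provided.  Benjamini–Hochberg adjustment is applied across all
reported proteins.

## Proteome complexity

A protein is unique to sample s when detected in s and nowhere else in the
analyzed cohort (cohort-wide definition; group-wise uniqueness is not the
default).  Counting is available at isoform (default) and gene level.  The
outcome association contrasts stage-IV-or-deceased samples against the
rest (both single-criterion contrasts are exposed) with the Wilcoxon
rank-sum test, no outlier removal.  The exact two-sided p enumerates the
full rank-sum null via dynamic programming over all C(n+m, n) assignments
and doubles the smaller tail, capped at 1; it is used automatically for
untied samples up to n+m = 30.  Ties fall back to mid-ranks with the
tie-corrected normal approximation and a 0.5 continuity correction (the
R convention).  With small integer counts the discrete/tied null makes the
test mildly conservative: the simulated type-I error at α = 0.05 sits
around 0.03–0.04 rather than 0.05.

## EV quality

Marker values are group-averaged on the log scale and min-max scaled to
[0, 1] per marker across columns (constant rows map to 0.5); a rank-based
variant (rank−1)/(n−1) sits behind a flag.  Min-max scaling is invariant
to adding a constant per column but not to arbitrary rescaling of a single
column; ordering of interior columns is preserved, which the tests assert
explicitly.  The EV score and contamination score are means of scaled
values over EV-flagged and non-EV-flagged markers.  Default panels ship as
data (YAML): tetraspanin-style EV markers (CD63, CD9, CD81, TSG101,
PDCD6IP, SDCBP, FLOT1, HSPA8) and organelle contamination markers (BCL2
mitochondrial, GOLGA2 Golgi, NUP98 nuclear, CANX ER); both are
user-replaceable, not canonical.  Particle-per-µg-protein purity uses the
literature bands: > 3×10¹⁰ high, 2×10⁹–2×10¹⁰ low; the uncited gap
(2×10¹⁰, 3×10¹⁰] is reported as "indeterminate" and ratios below the low
band as "below-low", making the classifier total on positive ratios.
NTA distributions are normalized to unit mass per sample on the common
0.5 nm grid and compared bin-wise with Welch t-tests (the unequal-variance
form, since nothing guarantees equal group variances); BH-adjusted values
are reported alongside raw p values, which carry the interpretation.
Zero-variance identical bins return t = 0, p = 1 by convention.

## Complete functional regulation analysis

Per category: the regulation p is a two-sided one-sample Student t of the
identified members' log2 ratios against 0 (Wilcoxon signed-rank behind a
flag); the fold change is 2^(mean log2 ratio); the enrichment p is the
hypergeometric upper tail P(X ≥ k) of the category within a query list
drawn from the quantified universe.  The default query is the
significantly regulated proteins (raw p < α) of the comparison: in deeply
quantified panels nearly every protein is identified somewhere, so
identification-based enrichment is degenerate (k ≈ K, p ≈ 1) and carries
no signal; enrichment among regulated proteins is the variant that makes
the joint filter informative.  An identification-based query can be passed
explicitly when identification itself differs between conditions.
Retention requires all three filters at once — enrichment p < 0.05,
|FC| > 2, regulation p < 0.05 — with raw (unadjusted) p values, as the
filters were defined; BH-adjusted enrichment values are additionally
reported.  Unpaired ratios are differences of group means of log2(x+1)
per protein; the universe is the quantified panel of the comparison, not
the whole proteome.  Categories with fewer than two identified members
are excluded with a log entry.  Star strata: * p < 0.05, ** p < 0.01,
*** p < 0.001.

## Cell population scores

Score(population, sample) = arithmetic mean of log2 abundances of the
population's markers present in the matrix, skipping markers undetected in
that sample (zeros are non-identification, not absence; no imputation).
Scores are equivariant under adding a constant to all log2 values.  Ten
populations ship by default (T cells, CD8 T cells, cytotoxic lymphocytes,
B lineage, NK cells, monocytic lineage, myeloid dendritic cells,
neutrophils, endothelial cells, fibroblasts) with user-replaceable marker
content.  Group summaries add average-linkage hierarchical clustering of
samples on Euclidean distances of their score vectors.  Scores default to
the quantile-normalized log scale.

## Cohort statistics

Counts with one-decimal percentages per group; "NA"/"unknown" levels are
display rows excluded from tests by default.  The χ² test is Pearson
without continuity correction; Fisher's exact test uses the conventional
two-sided rule (sum of table probabilities ≤ the observed), via direct
enumeration of fixed-margin tables for r×c shapes.  `auto` selects Fisher
when any expected cell count falls below 5.  The two conventions coexist
deliberately: published clinical tables mix them (the example cohort's
vital-status p matches uncorrected χ², its gender p matches Fisher on the
2×2 excluding NA), so the test is caller-selectable and both are exercised.

## Synthetic-data generator

The generator emulates the product of the emulated study, not its spectra:
12 controls + 12 cancer cases, ~3000 genes with 1 + Poisson(1.5) isoforms
each (~7500 rows), gene baselines Normal(20, 4) in log2 iBAQ units with
isoform scatter (sd 1) and cell noise (sd 1).  Detection is Bernoulli with
probability expit(2·(log2 abundance − 14)) — a logistic link putting
missingness in the low-abundance tail, ~10% zeros overall, and a
partial-detection band that yields a few sample-unique proteins per sample
naturally.  Nuisance structure: batch, gender and smoking enter as
per-sample offsets (sd 0.3 each) with group-conditional covariate
frequencies patterned on the emulated cohort; 5/12 cancer cases are
stage-IV and deceased (the two travel together, as in the cohort).

Planted signals: (i) `n_de` proteins shifted ±`de_log2fc` in cancer with
balanced directions — real dysregulation is bidirectional, and a one-sided
plant would be partially absorbed by quantile normalization; planted rows
are drawn from reliably detected proteins (near-certain detection even
2.5 noise-sd below baseline) outside the top abundance decile, so recovery
measures the statistics rather than the missingness process or the
rank-saturation of the normalizer; (ii) Poisson(`extra_unique_mean`)
proteins per poor-outcome sample detected only there — the mechanism
behind the complexity signal; (iii) marker panels spiked at controlled
log2 levels with optional per-sample shifts; (iv) NTA particle sizes drawn
LogNormal(ln(mode) + σ², σ) so the analytic density mode equals `mode_nm`
exactly (the sampled argmax bin wanders a few nm because the density is
flat near the mode).  One global seed drives deterministic child
generators, so any stage reproduces in isolation.

What the generator does not emulate: correlated protein modules,
peptide-level effects, intensity-dependent variance trends, batch ×
protein interactions, or real marker biology.  Passing recovery tests
therefore demonstrates that the statistics behave as designed under the
stated model — not that the pipeline's power on real BAL-EV data equals
the simulated rates.

## Problem sizes and calibration targets in the checks

The recovery checks run at the study's design size (12 + 12): differential
expression on 3000 single-isoform proteins with 100 planted two-fold
effects over 50 seeds (mean sensitivity > 0.8 at adjusted p < 0.05, mean
empirical FDR ≤ 0.10); CFRA on 1000 proteins with a 30-member category
planted at +1.5 log2 over 100 seeds; complexity association on
1000-protein cohorts (100 seeds power, 500 seeds null).  Exact-test
oracles enumerate all group sizes n+m ≤ 10 (Wilcoxon), fixed-margin tables
with n ≤ 40 (Fisher), and subset draws with N ≤ 15 (hypergeometric).

## Known limitations

- Quantile normalization attenuates strongly asymmetric shifts in sparse
  tail regions (documented above); effect sizes estimated after it are
  mildly conservative.
- The exact Wilcoxon path requires untied observations; tied integer
  counts always use the normal approximation, which is conservative for
  very small counts.
- The enumerated r×c Fisher test is exponential in table size and intended
  for cohort-scale tables (tens of samples, few levels).
- The covariate-corrected model spends degrees of freedom and contrast
  precision in a 24-sample design; with global (column-constant) nuisance
  effects, quantile normalization already removes them, and the two-group
  fit on normalized data is the higher-powered configuration used in the
  recovery checks.
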