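# Methods

## Problem setting

Serum small-RNA sequencing of a small case/control cohort (the reference
design is 7 cases vs 7 controls) yields genome-aligned reads of 18–48 nt
deriving from microRNAs, 5′ tRNA halves, YRNA fragments and a minor
rRNA/snRNA/snoRNA remainder. The pipeline classifies reads into these
classes, tests per-feature abundance differences between groups under a
negative-binomial model, screens the differentially abundant (DA) miRNAs'
target genes for "overtargeting", and correlates normalized levels with
tumor stage.

## Read classification

Coordinates are 0-based half-open internally (BED convention); printed
table fixtures use 1-based inclusive coordinates and are converted at the
I/O boundary. Each read is assigned to the same-strand feature with
maximal overlap of at least `min_overlap_frac` (default 0.5) of the read
length. Antisense overlaps never count: sncRNA fragments are
strand-specific by biogenesis. Ties break by overlap length, then class
priority miRNA > tRNA > YRNA > rRNA > snRNA > snoRNA, then lowest feature
id, so assignment is single and deterministic, mirroring a
best-single-alignment mapping policy. rRNA/snRNA/snoRNA reads are
classified but not carried into differential testing.

End assignment is strand-aware: a fragment is 5′-derived when its
biological 5′ terminus lies within `end_window` nt (default 5) of the
feature's 5′ terminus, 3′-derived analogously, and ambiguous (`none`) when
both or neither end qualifies. 5′ tRNA halves are counted per tRNA locus
from tRNA-classified reads of 30–33 nt whose 5′ terminus is within
`start_tolerance` nt (default 1) of the gene's 5′ end; 3′ tRNA fragments
are deliberately not counted. No tolerance is standard in the field for
either window; the defaults are chosen tight and exposed in the config.

Class-composition differences between groups are tested with a Pearson
chi-square test of independence on the class-by-group contingency table
(no continuity correction), df = k − 1 for k classes.

## Differential abundance

The chain is the canonical single-factor count workflow:

1. **TMM normalization.** Reference library: upper-quartile count
   proportion closest to the mean. Per-library factor: 2 to the
   precision-weighted trimmed mean of M-values against the reference
   (trim 0.30 on M, 0.05 on A; delta-method binomial weights), re-centered
   to geometric mean 1. Factors agree with the reference implementation of
   TMM to numerical precision (cross-checked in the test suite).
2. **CPM.** Counts per million of effective library size
   (lib size × factor). With a prior count (default 2) the prior is
   scaled per library in proportion to effective size, keeping constant
   features flat on the log scale. The reported `CPM` column is the mean
   over all libraries on the CPM scale.
3. **Dispersion.** Counts are rescaled to the geometric-mean effective
   library size ("pseudo-counts") — a documented simplification of
   quantile adjustment — and the NB conditional log-likelihood, summing
   over both groups, is maximized on [1e-6, 10] in log-dispersion space
   (dense grid plus local quadratic-vertex refinement). Tagwise estimates
   maximize the per-feature likelihood plus a shared-likelihood term with
   weight `prior_df / residual df` (prior_df default 10): the weighted
   conditional likelihood with prior_df pseudo-observations at the common
   value. prior_df → ∞ recovers the common value for every feature;
   prior_df = 0 gives per-feature conditional MLEs. These estimators are
   validated by parameter recovery on simulation (relative error < 20% at
   2000 features; in practice ~3%), not bit-equality with other tools.
4. **Exact test.** Conditional on a feature's rounded total of rescaled
   group sums, the case-group sum follows a negative hypergeometric law
   with shapes n1/φ and n2/φ; the two-sided p-value sums probabilities of
   all splits no more likely than the observed one (ties included, within
   a 1e-9 log tolerance). The log-pmf uses exact running sums of
   log(r + k) rather than lgamma differences, so the Poisson limit
   (r → ∞) keeps symmetric splits tied exactly. Features with all-zero
   counts are dropped before testing with a logged count.
5. **BH adjustment** (statsmodels step-up) and summary in the printed
   convention: `fc_signed = sign(log2fc) · 2^|log2fc|`, so −3.4 means
   3.4-fold down in cases; log2fc is log2 of the ratio of prior-augmented
   group mean CPMs (positive = up in cases).

Significance thresholds mirror the reference workflow's usage: P < 0.05
with FDR < 0.15 for known miRNAs and FDR < 0.10 for novel ones; both are
config values, never hardcoded in stage logic.

**MDS.** Between-sample distance is the root-mean-square of the `top_k`
(default 500) largest absolute log2-CPM differences for that pair
("leading logFC"); coordinates come from classical (Torgerson) MDS on the
double-centered squared-distance matrix, with signs fixed so each
dimension's largest-magnitude coordinate is positive.

## Overtargeting

The interaction universe is (prediction source A ∩ prediction source B) ∪
validated pairs, deduplicated, with provenance `predicted`, `validated` or
`both`. Identifier harmonization is exact string match after upper-casing;
alias resolution is out of scope.

The per-gene statistic is formalized as a **miRNA-draw** hypergeometric:
population M = miRNAs in the universe, successes K = DA miRNAs present in
it, draws n = miRNAs targeting the gene, upper tail P(X ≥ x) including the
observed value. An edge-draw alternative (counting interaction events
rather than distinct miRNAs) exists; the miRNA-draw form is the standard
reading and is locked in. Genes targeted by zero universe miRNAs are
excluded (undefined draw). BH runs separately within the up- and
down-regulated screens — two separate families matching the two reported
gene lists — and a gene is flagged at p < 0.01 and FDR < 0.05 (defaults).

Census filtering is a plain membership restriction to a cancer-gene-census
list. The enrichment stage is a plain hypergeometric gene-set
over-representation test with BH across collections — a deliberate
replacement for fuzzy functional-annotation clustering, which is out of
scope. Networks are bipartite miRNA–gene graphs; gene nodes carry the
expected tissue regulation (opposite to the circulating miRNA direction),
miRNA nodes a hub flag at degree ≥ 3 within a category subnetwork; exports
are canonical-ordered GraphML (lossless round-trip) and SIF.

## Clinical association

The T component of a TNM string (`T[1-4]N[0-3]M[01]`) is treated as a
numeric 1–4 score. Feature levels (default log2-CPM; configurable) are
gated by a Shapiro–Wilk test at alpha 0.05: Pearson correlation when
normality is not rejected, Spearman otherwise — which also makes the
ordinal stage encoding safe. Cohort summaries report per-group n, mean age
and sample (n−1) SD to one decimal; a single-subject group reports SD as
not available.

## Synthetic data

The generators emulate the study conditions so every stage has planted
ground truth:

- **Counts**: baseline feature log-means uniform on [log 5, log 5000]
  (spanning the CPM range of printed serum tables, ~7 to ~39,000);
  library sizes log-uniform on 1e6–5e6 (per-sample depths are rarely
  reported for serum libraries; the window is a parameter); NB counts with
  variance μ + φμ²; a `frac_da` subset of features receives ±`log2fc`
  shifts in cases with sign drawn 50/50 (printed tables contain both
  directions). Default dispersion 0.2 — a typical biological coefficient
  of variation (~0.45) for human serum samples.
- **Alignments**: reads placed inside non-overlapping synthetic features;
  miRNA lengths peak at 20–24 nt, tRNA halves at 30–33 nt anchored to the
  5′ terminus, YRNA fragments 25–33 nt anchored to a random end; the
  default class mix is miRNA 50%, YRNA 38%, tRNA 10%, other 2%. The
  pipeline's simulate stage uses shifted mixes between groups (miRNA share
  rising in cases) to exercise the composition chi-square.
- **Universe**: background edges appear independently at `density`;
  planted genes receive DA-miRNA edges at min(1, density × boost). The
  default DA-miRNA share of the universe is one half, reflecting that a
  real universe is built from the DA miRNAs' own target predictions plus
  validated pairs, so DA miRNAs dominate its miRNA set. At boost = 1
  planted genes are statistically indistinguishable from background
  (null calibration); boost = 4 is the frozen power operating point.
- **Cohort**: cases carry `T{t}N{n}M0` strings, controls none.

Every generator is a pure function of its arguments including the seed
(one numpy Generator per call, no global state); the pipeline derives all
stage seeds from a single config seed via `SeedSequence`.

What the synthetic data does **not** model: sequence content (no FASTQ,
error models or adapters — alignment simulation ends at BED records),
multi-mapping ambiguity, overlapping features, GC or length biases,
batch effects, and correlated features. Passing tests therefore establish
the correctness and calibration of the statistical machinery under the
declared model, not robustness to artifacts of real sequencing data.

## Numerical choices and problem sizes

- Dispersion search space [1e-6, 10], 257-point log grid, quadratic-vertex
  refinement on the five grid points around each maximum; boundary maxima
  keep the grid value.
- Exact-test tie tolerance 1e-9 in log-probability; totals are rounded to
  the nearest integer after rescaling.
- Chi-square requires ≥ 2 classes with nonzero totals and no zero expected
  cells; correlation requires ≥ 4 pairs and non-constant inputs; degenerate
  inputs raise typed errors rather than returning NaNs.
- Validation simulations use 1000 null features for type-I calibration,
  2000 features × 10 seeds for dispersion recovery, 400 features × 10
  seeds for DA sensitivity, 20 seeds for overtargeting power and 10 for
  MDS separation — sizes chosen so the full suite and the acceptance
  script each run in well under a quarter hour on one CPU while leaving
  the binomial error on every estimated rate far below its acceptance
  margin.

## Known limitations

- The exact test rescales counts to a common library size by plain
  proportional scaling rather than quantile adjustment; p-values track
  the reference implementation within ~2% relative on moderate counts
  (cross-checked against edgeR in the test suite) but are not bitwise
  identical.
- The tagwise shrinkage weight uses the across-feature average likelihood
  rather than locally moderated (abundance-binned) sharing.
- Duplicate-mature-sequence miRNA families (identical read support) should
  be aggregated into one statistical unit upstream; the DA stage treats
  rows as independent features.
- The overtargeting screen's miRNA-draw formalization ignores multiplicity
  of validated+predicted support per pair; provenance is carried as an
  edge attribute but does not weight the test.
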