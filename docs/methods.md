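# Methods

## Data model

The central object is a nonnegative protein × sample abundance matrix with
a case/control label per sample. Values are treated as
spectral-count-like: nonnegative, additive across identifiers of the same
gene, and with non-detection recorded as exact 0 (not a missing-value
sentinel) — an undetected protein contributes a zero to group means, which
is what makes "case-exclusive" (control mean exactly 0) a well-defined
category. Whether the upstream quantification produced summed MS/MS
spectral counts or search-engine intensity scores does not matter to any
operation here; both ride in the same matrix type.

Log2 transformation uses a +1 pseudocount so a zero stays at log2 value 0,
preserving the "absent < everything detected" ordering. High/low
abundance partitioning compares the per-protein mean log2 intensity to a
cutoff (default 12): strictly above is *high*, equal-or-below is *low*.
The strict comparison direction matters only for proteins exactly at the
cutoff and mirrors the usual "above" / "equal to or below" phrasing.

## Rank-sum testing with zero inflation

Per protein, the one-sided Wilcoxon rank-sum test asks whether case
abundances are stochastically greater than control abundances. At cohort
sizes like 13 vs 15 with blocks of tied zeros, the normal approximation is
unreliable, so the null is computed exactly: mid-ranks are assigned to the
pooled sample, doubled to integers, and the distribution of the case
rank-sum over all C(n, n₁) relabelings is built by a subset-sum dynamic
program (the Streitberg–Röhmel shift algorithm). Counts stay below
C(30, 15) < 2⁵³, so float64 arithmetic is exact. The distribution is
cached per tie pattern — in a 640-protein cohort only a few dozen distinct
patterns occur, so the exact test over a whole matrix costs milliseconds.
For pooled sizes above 30 the tie-corrected normal approximation with
continuity correction is used and tagged in the result.

The test depends only on ranks, so it is invariant under any strictly
monotone transform of the data; testing on linear or log2 scale is
equivalent. No multiple-testing correction is applied by default, matching
the discovery procedure this implements (raw p < 0.05 filtering);
Benjamini–Hochberg q-values are available as an explicit opt-in.

### Fold changes and the filter cascade

Fold change is the ratio of linear-scale group means. Control mean exactly
0 with a positive case mean flags the protein CASE_EXCLUSIVE (written as
`***`); both means 0 is UNDEFINED. The cascade selects, per fold tier,
genes with p < α and fold change beyond the tier; the 1.2 and 2.0 tiers
use a strict comparison (">1.2-fold", ">2-fold") while the 3.0 tier is
inclusive ("3-fold or higher"), and case-exclusive proteins pass every
tier. Tiers are nested by construction.

## AUC and marker panels

Marker discrimination is the Mann–Whitney AUC: the probability a random
case value exceeds a random control value, half credit for ties, computed
from mid-ranks; it equals the trapezoidal area under the empirical ROC
curve (asserted to 1e-12 in the tests). For a combined panel, the
combination rule is deliberately conventional: ridge-penalized logistic
regression (fixed small penalty, C = 100) on per-marker standardized log2
abundances. The penalty keeps separable fits finite and deterministic; the
score is a monotone link of the linear combination, so the panel AUC
depends only on the linear part. An unweighted z-score-sum combiner is
available as an alternative. Panel AUC is reported in-sample (no
cross-validation) by default, matching how small discovery studies report
combined-marker performance; this is optimistic by construction and the
limitation is inherited deliberately.

Confidence intervals come from a stratified percentile bootstrap (default
2000 replicates): samples are resampled with replacement within each
group, the panel is refit and rescored per replicate, and the interval is
the percentile range truncated to [0, 1] — which naturally produces
asymmetric intervals with an upper bound pinned at 1 for strong panels.

## Clustering

Sample (or gene) profiles are compared by Pearson correlation distance
d = 1 − r ∈ [0, 2]. Ward's minimum-variance criterion is applied *directly*
to these dissimilarities via the Lance–Williams recurrence (the "ward.D"
convention) rather than to squared Euclidean distances, since 1 − r is not
Euclidean. Implementation: scipy's Ward linkage squares the supplied
dissimilarities inside its update, so running it on √d performs exactly
the ward.D recurrence on d with an identical merge order (√ is monotone);
the reported heights are recovered by squaring. Ward's coefficients make
the heights monotone, so trees have no inversions. Ties in merge order are
resolved by scipy's deterministic scan order. Zero-variance profiles have
undefined correlation: gene-axis clustering drops them with a warning,
sample-axis clustering refuses with an error naming them. Trees export to
Newick with branch lengths derived from merge-height differences.

## Network statistics

Edge enrichment of a protein set against a background interaction graph
uses the simplest defensible null: uniformly random node subsets of the
same size, not degree-preserving — mirroring the "random set of similar
size drawn from the genome" comparison that database front-ends report.
The expected edge count is the null mean and
p = (1 + #{null ≥ observed}) / (n_perm + 1), so p is never exactly 0. The
permutation loop is vectorized (boolean membership matrix against the edge
index arrays), making 10⁴ permutations on a few-thousand-edge graph take
well under a second. The clustering coefficient is the unweighted mean
local coefficient over the query-induced subgraph with degree-<2 nodes
counted as 0. Term enrichment is the closed-form hypergeometric upper
tail against user-supplied annotations (GMT) over a user-supplied
background, BH-adjusted across terms; no annotation corpus ships with the
package.

## Vesicle QC

Modal particle size is the center of the most populated fixed-width
histogram bin (default 1 nm, edges at integer multiples of the width, ties
to the smaller bin) — deterministic and close to NTA-instrument
convention, rather than a kernel density estimate. Note the estimator's
single-draw noise: a log-normal size distribution is flat near its peak,
so at 10⁵ particles the 1-nm histogram mode fluctuates by several nm;
validation therefore averages the estimate over independent draws. The
exosome size window defaults to [30, 200] nm (closed) with the stricter
endosomal 30–150 nm definition available through the bounds arguments.
Yield is concentration × dilution factor / plasma input volume; purity is
the Webber–Clayton ratio of total nanoparticle count to protein mass
(particles/µg).

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
with defaults set to the discovery-study design: 13 cases vs 15 controls,
640 proteins, 80 of them in a high-abundance mode. Per protein, a base
log2 level is drawn from a two-component normal mixture (high mode mean
15.5, low mode mean 7.0, between-protein SD 1.2) — placing the modes well
either side of the log2 = 12 partition cutoff so the 80/560 split is
reproduced — and per-sample values add N(0, 0.8²) log2 noise
(≈60% CV, a realistic between-subject plus technical spread for plasma
spectral counts) before exponentiation to the linear scale.

Missingness is intensity-dependent (missing-not-at-random, as in real
spectral counting): detection probability follows a logistic curve in the
underlying log2 intensity with width 1.0, anchored so a protein at the
low-mode center is undetected with probability `dropout_rate` (default
0.2). High-abundance proteins essentially never drop out, and boosting a
protein in cases also improves its detection there — which is how genuine
case-exclusive detection patterns arise. Because dropout depends only on
intensity, a cohort with no planted effects remains exchangeable between
groups, so downstream type-I error calibration is meaningful.

Planted effects: `n_diff` low-mode proteins (default 108, the scale of a
real discovery hit list) have their case values multiplied by
2^`planted_log2fc` (default 2.0) before dropout; the first `n_exclusive`
of them (default 21) are additionally zeroed in every control sample.
Companion generators produce a cell-line EV reference set with a
controlled overlap fraction plus novel symbols, an unfractionated-plasma
reference with independent abundances, log-normal NTA particle diameters
parameterized by their mode (mode = exp(µ − σ²), so µ = ln(mode) + σ²),
and an Erdős–Rényi background graph with a denser planted module. Every
generator uses one explicitly seeded stream; identical seeds reproduce
outputs bitwise.

### What the simulation does and does not show

The generator reproduces the features the pipeline's logic depends on —
bimodality, zero inflation, case-exclusivity, planted effect sizes,
reference-set overlap, module-bearing graphs — but not batch structure,
correlated protein modules (co-regulation), peptide-level identification
noise, or abundance-dependent variance beyond the dropout curve. Passing
recovery tests therefore demonstrates the pipeline's statistical
machinery, not performance guarantees on clinical data. At the default
noise level, a planted 4-fold marker at n = 13/15 has an AUC around
0.85 ± 0.07 and an observed fold change that scatters widely around 4, so
exact recovery of a 4-marker set against 636 null proteins succeeds in
roughly two-thirds of cohorts — small-cohort discovery is genuinely noisy,
and the simulation reflects that.

## Numerical and design choices

* Exact-test threshold n₁+n₂ ≤ 30: covers the target cohort size; beyond
  it the DP table grows and the normal approximation is already accurate.
* Reported percentages round half away from zero to integers (the style
  of published count summaries); machine outputs keep full precision.
* Gene symbols are matched after upper-casing both sides; no ortholog or
  accession-version reconciliation is attempted.
* NSAF without a length table falls back to L = 1 (plain normalized
  spectral fraction) and labels the output accordingly.
* The pipeline derives one seed per stochastic stage from the configured
  seed and records all of them; rerunning a configuration reproduces the
  summary JSON byte for byte.
* Pipeline problem sizes default to the study design (640 × 28); the
  acceptance script's simulations use 20 null cohorts and 5 recovery
  cohorts, enough to pin calibration within Monte-Carlo error at that
  design size.

## Known limitations

* In-sample panel AUC is optimistic; k-fold CV exists in the API surface
  as an extension but is not the default, by design.
* The AUC tie convention (0.5 credit) yields 0.5 + k/26 for a 13-case
  exclusive marker; published per-protein AUC values produced by other
  tie/zero conventions may differ slightly and are not asserted.
* The edge-enrichment null does not condition on the degree sequence; a
  degree-aware null would be stricter for hub-heavy query sets.
* The histogram mode estimator is intentionally simple; for narrow
  questions about the size distribution's peak, average over draws or
  widen the bins.
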