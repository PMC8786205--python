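# Methods

## The exclusivity model

The unit of analysis is a binary case × gene mutation matrix over a fixed
cohort of n cases; gene g is "mutated" in a case when the case carries at
least one qualifying variant (post consensus, impact and gene filters) in g.
Cases with no qualifying mutation stay in the matrix as all-zero rows:
conditional probabilities are properties of the cohort, not of the mutated
subset, and removing quiet cases would bias every CP upward.

For an ordered pair (A, B), CP(A, B) = P(¬A | B) = #(B ∧ ¬A)/#B. The pair is
ordered — CP(A, B) and CP(B, A) generally differ — and CP is undefined when B
has no carriers (such pairs are skipped with a log entry, not errored).

### The permutation null

The null re-assigns, independently per gene, the gene's a_g mutated cases to
a uniformly random subset of size a_g, and recomputes CP; 2000 permutations
per ordered pair by default. Under this scheme the count of B-carriers that
also carry A is exactly Hypergeometric(n, a_A, b), so the implementation
draws that overlap directly rather than materialising case subsets — the
distribution is identical and the sampler is two orders of magnitude faster.
The exhaustive-enumeration test (all C(n, a)·C(n, b) placements at n ≤ 8)
checks the sampled null against subset enumeration, keeping the fast path
honest. The null mean obeys the closed form E[CP] = (n − a_A)/n, which the
suite verifies on random fixtures.

This per-gene null preserves per-gene mutated-case counts but **not**
per-case mutation burdens. Whether burdens should be held fixed is a real
modelling choice: hypermutator cases make co-occurrence more likely than the
per-gene null expects, which can inflate exclusivity sigma. A
margins-preserving alternative (`null="curveball"`, repeated trades between
gene case-sets that conserve both row and column totals) is provided as a
sensitivity check; the per-gene scheme remains the default because it is the
minimal reading of "randomly distributing the exact mutations amongst the
cases" and is what the closed-form diagnostics above apply to.

### Sigma, p-values, tiers

σ = (CP_obs − null mean)/null SD, signed so that positive σ is the
exclusivity direction. p-values are two-sided standard-normal tails at |σ|
(σ = 2 ↦ 0.0455, printed 0.05; σ = 3 ↦ 0.0027, printed 0.003), extrapolated
from the fitted normal rather than the empirical rank so that pairs far
outside the null remain comparable (an empirical rank saturates at
1/2000). Each null is Shapiro–Wilk-tested at α = 0.05; rejected pairs are
flagged `non_normal` and carry their empirical percentile alongside the
normal-theory p, but are not dropped. With discrete hypergeometric values at
2000 samples the test rejects routinely even when the normal approximation
is serviceable, so the flag is advisory, not a filter. `outside_null`
records whether CP_obs exceeds every permuted value.

An unordered pair becomes an edge when both ordered σ ≥ 1.5 and at least one
≥ 2 (i.e. p ≤ 0.05); the tier comes from the weaker side — min σ > 2.7 or
both directions outside the null gives `double` (the reason is recorded),
min σ ≥ 2 `solid`, else `dashed`. Per-pair permutation seeds are derived by
hashing the master seed with the unordered pair symbols, making the sigma
table invariant to gene order and reproducible pair-by-pair.

## Upstream filters

* **Cohort**: cases must match a configurable histology string (default
  "muscle invasive urothelial carcinoma") and stage ii/iii/iv; stage strings
  are normalised from common dialects, unmapped values become "other" and
  are excluded. Cases absent from the clinical table are dropped. Case
  identity is the 12-character TCGA barcode prefix (sample/portion suffixes
  denote aliquots of the same case); non-TCGA identifiers pass through.
* **Impact**: variant impact is taken as annotated (HIGH/MODERATE/LOW/
  MODIFIER, matched case-insensitively); the analysis default keeps
  HIGH + MODERATE. Impact is not re-derived from consequence terms.
* **Consensus**: a variant is the exact (case, chromosome, start, ref, alt)
  tuple; no position fuzzing or indel normalisation. Duplicate rows within a
  pipeline count once. The deduplicated record takes the modal impact across
  supporting callers, ties resolved toward the more severe class.
* **Gene panel**: restriction to a DDR/CM list. The bundled 30-gene panel
  carries best-effort DDR/CM/both class annotations used only to label
  network nodes (square/oval/rounded in the DOT export); they affect no
  statistic.
* **Chance-rate (FDR) threshold**: the observed mutation total is dropped
  uniformly onto (gene, case) slots over a 20,500-gene genome, binarised,
  and the maximum per-gene case rate recorded per iteration; the threshold
  is the mean of those maxima (an upper quantile of the per-gene rates is
  available as an alternative statistic). Genes whose observed rate does not
  *exceed* the threshold are removed. The defining statistic and the
  mutation total to redistribute are exposed as configuration rather than
  fixed, because a "chance ceiling" admits more than one reasonable
  definition; the estimator's Monte Carlo SE is always reported. Default
  iteration count is 10⁶; desk-scale runs and tests use 10³–10⁴, which the
  reported SE shows to be amply precise for thresholding.

## Synthetic cohorts

The generator plants pairwise exclusivity of strength e for a pair (A, B)
with marginals p, q by drawing each case's joint status from the 2 × 2
distribution with P(A ∧ B) = (1 − e)·p·q and margins preserved — e = 0 is
independence, e = 1 forbids co-occurrence, and per-gene frequencies stay at
their configured values, which is exactly what the permutation null
conditions on. Post-hoc deletion schemes were rejected because they distort
margins. A gene may appear in at most one planted pair (overlapping pairs
have no common joint distribution in this scheme); exclusivity cliques are
out of scope.

Each true (case, gene) event becomes one variant with coordinates unique to
the event and shared across pipelines (1-based positions in a per-gene locus
block). Each pipeline drops a true call with probability 1 − sensitivity and
adds, per case, a spurious call with probability equal to its false-call
rate; spurious calls get fresh unique coordinates (a reserved coordinate
block) so they can never accidentally gain cross-pipeline support. Impact
labels are drawn per variant from a configurable distribution, independent
of gene and case.

That independence has a consequence worth knowing: the impact filter removes
carriers whose only variant drew a LOW/MODIFIER label, attenuating planted
exclusivity by roughly the filtered fraction. The `analysis/` cohort shows
this honestly — the strong planted pair (e = 0.95 at ~27 % frequency)
survives every subset as a double edge, while weaker pairs (e ≤ 0.8 at
≤ 18 %) drop below the dual-σ criterion after filtering. Real cohorts, where
exclusivity presumably acts through the functional mutations themselves,
should attenuate less.

The expression simulator scales target genes by (1 − effect) in cases
carrying a true mutation in either driver, before adding Gaussian noise;
controls keep the baseline (default 10, arbitrary units on a normalised
scale). The classifier bins each gene by its signed fractional change from
the wild-type mean in both driver-mutant groups: `little` (both < 20 %),
`modest` (one in [20 %, 40 %), the other < 20 %), `coordinate_decrease`
(both negative, beyond the previous bins), `other`. Precedence is
little → modest → coordinate_decrease → other; the decrease summary averages
each coordinate gene's mean |change| across the two groups. Cases mutant in
both drivers join both mutant groups by default (rare under exclusivity;
switchable).

What the synthetic cohort does **not** emulate: mutational signatures and
hotspots, copy-number change, per-case burden heterogeneity
(hypermutators), subclonality, caller-specific error profiles beyond a flat
sensitivity/false-call rate, and impact labels correlated with the planted
biology. Passing tests therefore demonstrate the statistics and the
plumbing under the stated model, not robustness to those real-data
features — the curveball null and the non-normality flags are the provided
levers for probing the first of them on real inputs.

## Problem sizes and numerical choices

Defaults: 2000 permutations per ordered pair; chance-rate bootstrap 10⁶
iterations (desk-scale runs 2·10³–2·10⁴); the calibration experiment uses
200 cohorts of 400 cases × 10 genes at 500 permutations, sizes at which the
whole suite plus the acceptance script completes in well under a minute on
one core. Sample (ddof = 1) standard deviations throughout (CV and null SD);
the CV denominator is the per-case mean count, flagged undefined at mean 0.
Quartiles are linear-interpolation (type 7). Degenerate pairs (a_g ∈ {0, n},
null SD 0) are excluded with a marker, not errored. High-impact-only
analysis is refused on the stricter consensus tiers unless forced — too few
high-impact calls survive there for a stable null.

## Known limitations

* The two orderings of a pair share the same observed overlap, so "both
  directions significant" is closer to one test than two; calibration is
  checked at the unordered-pair level.
* Normal-tail p-values below ~10⁻⁷ are extrapolations far beyond what 2000
  permutations can empirically support; treat them as ordering, not as
  literal tail mass.
* The chance-rate threshold depends on which mutation total is
  redistributed (per-pipeline, union, per-subset); this is a configuration
  input, and cross-study comparisons should state it.
* Variant matching is exact on coordinates and alleles; pipelines that
  left-align indels differently will under-count consensus support.
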