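# Methods

## The conditional false discovery rate

For a variant with target-trait p-value $p_1$ and conditioning-trait p-value
$p_2$, the conditional FDR is the probability that the variant carries no
true association with the target trait given that both observed p-values are
as small or smaller than observed,

$$\widehat{\mathrm{cFDR}}(p_1, p_2) \;=\; \min\!\Big(1,\; \frac{p_1 \, N(P_2 \le p_2)}{N(P_1 \le p_1,\, P_2 \le p_2)}\Big),$$

with counts $N(\cdot)$ taken over a reference set of variant pairs.  This is
the empirical-Bayes FDR generalized to two traits: the numerator
$p_1 N(P_2 \le p_2)$ estimates the expected number of target-null variants in
the rectangle $(P_1 \le p_1, P_2 \le p_2)$ under a uniform null, and the
denominator counts the variants actually observed there.  When the
conditioning trait shares causal variants with the target, the stratum
$P_2 \le p_2$ is enriched for true target associations, the denominator grows
faster than the numerator, and variants with shared support are promoted
relative to an unconditional FDR — which is the entire point of
pleiotropy-informed discovery.

We implement the raw inclusive-counting form (all comparisons $\le$) rather
than a smoothed or grid-interpolated lookup: the counting form is the estimator's
defining expression, is exactly testable against an $O(M^2)$ double loop
(the suite checks equality, not approximation, on hundreds of random
instances), and requires no smoothing parameters.  Two practical guards:

* **Minimum stratum count** (default 50).  If the conditioning stratum
  $N(P_2 \le p_2)$ holds fewer reference pairs than this, the threshold is
  relaxed to the smallest $p_2' \ge p_2$ achieving the minimum (falling back
  to the whole reference set), preventing near-zero-variance estimates from
  tiny strata.
* **Cap at one** (on by default): the estimate is a probability.

An optional monotonization (cumulative minimum along decreasing $p_1$) is
off by default.  With an uninformative conditioning trait (all $p_2$ equal)
the estimator reduces exactly to $p_1 M/\mathrm{rank}(p_1)$, and switching
monotonization on makes it identical to Benjamini–Hochberg adjusted
p-values; the suite asserts both reductions exactly.

## Averaging over random LD pruning

Linkage disequilibrium makes neighbouring variants dependent, which distorts
empirical counts.  Following standard practice for this estimator family,
the reference set for each of `n_iterations` (default 500) iterations is a
random LD-pruned subset: a uniformly random permutation is walked greedily
and a variant is kept iff its $r^2$ with every already-kept variant is
strictly below `prune_r2` (default 0.2).  The cFDR is evaluated at **every**
variant against that iteration's reference, and the reported value is the
per-variant mean across iterations (the between-iteration SD is reported as
provenance).  Iteration $k$ uses seed `base_seed + k`, so results are
bit-reproducible and independent of any parallel execution order.

Complexity: pruning is $O(\text{edges})$ per iteration; the joint counts are
computed offline by sorting the reference by $p_2$ and sweeping a Fenwick
tree over $p_1$ ranks, $O((M+R)\log R)$ per iteration instead of the naive
$O(MR)$.  Both inner loops are numba-compiled.

## Locus identification

Variants below the relaxed cFDR threshold (default 0.10) are clumped
greedily in ascending cFDR (ties broken by ascending $p_1$, then variant
ID): a variant becomes a lead iff its $r^2$ with every existing lead is
below `clump_r2` (default 0.1), otherwise it joins the first lead it tags.
Leads within `merge_window` (default ±250 kb) on a chromosome are merged by
**single linkage** — "within 250 kb of each other" is ambiguous between
single and complete linkage, and single linkage (chains collapse) matches
common locus-merging practice; it is asserted explicitly in the tests.  The
locus representative is the merged lead with the smallest cFDR; locus
boundaries are the member-position extremes (no standard definition exists,
so the widest defensible span is used).  Loci are tiered at cFDR < 5%
(tier 1) and < 10% (tier 2).  Conditioning on two cohorts of the same
secondary trait is handled as two independent cFDR analyses whose lead lists
are pooled and re-merged with the same rule; re-merging a merged set is a
no-op (idempotence is tested).

## Exclusion regions and 1-df recomputation

Before estimation, variants inside regions of long-range complex LD are
removed; the built-in default set is the MHC (chr6:25,119,106–33,854,733)
and the 8p23.1 inversion (chr8:7,200,000–12,500,000), GRCh37, interpreted as
1-based inclusive and stored 0-based half-open.  When a source scan's
p-values are deflated relative to the Wald statistic, `recompute_p_1df`
replaces them with the upper tail of a 1-df chi-square at $(\beta/se)^2$.

## Replication testing

Lead variants are looked up in an independent cohort harmonized to the
discovery allele frame (allele-order swaps flip the replication effect sign;
strand-ambiguous A/T and C/G variants keep their p-value but their effect
direction is reported as undetermined).  Nominal replication is
$p < 0.05$; FDR replication applies Benjamini–Hochberg across the tested
leads only (leads absent from the replication data are excluded from both
the adjustment and the trial count).  Enrichment over chance is the exact
one-sided binomial upper tail $P(X \ge k)$ with $X \sim \mathrm{Bin}(n,
0.05)$ — for 5 hits among 13 tested leads this is $2.9\times10^{-4}$.

## Cross-trait diagnostics

* **Fold enrichment**: fraction of target-associated variants
  ($p_1 < 0.05$, strict) among conditioning-associated variants
  ($p_2 < 0.05$) divided by the fraction among all variants; equals 1 under
  independence.
* **Genomic Spearman correlation**: across independent LD blocks, the
  per-block statistic per trait is $-\log_{10}$ of the block's minimum
  p-value, and $\rho$ is the Spearman correlation of the two block-statistic
  vectors.  The block-minimum statistic is the simplest choice consistent
  with per-block summarization; it is isolated in one function so
  alternatives (mean $-\log_{10} p$, lead-variant p) can be swapped, and
  because $\rho$ is a rank statistic it is invariant to any strictly
  monotone transform of either trait's p-values.
* **Robust trend**: the line through per-trait $(\rho, \text{fold})$ points
  is fitted by iteratively reweighted least squares with Huber weights
  (tuning constant 1.345 for 95% Gaussian efficiency, coefficient tolerance
  $10^{-8}$, at most 50 iterations, MAD residual scale); the slope CI and
  p-value come from the final weighted fit's t-statistic.  The loop is
  cross-checked against `statsmodels` RLM in the suite.

## The synthetic-data generator

Real two-trait GWAS inputs are large and access-controlled, so the package
ships a generator that emulates their statistical structure at desk scale.
Effects are injected at the z-score level (non-centrality
parameterization) — the pipeline only ever sees summary statistics, and
z-level simulation makes calibration and power targets analytically
controllable.  The genome is `n_blocks` independent blocks of
`snps_per_block` variants; each block draws a class from the four-groups
mixture (null / target-only / conditioning-only / shared) and, if non-null,
one causal variant.  The causal z is $N(\delta, 1)$; block-mates see
$z_j = \sqrt{r^2}\, z_{\text{causal}} + \sqrt{1-r^2}\,\varepsilon_j$, so any
within-block pair of z-scores has squared correlation $r^2$ — exactly what
the accompanying LD reference reports.  Shared blocks draw
$(\delta_1, \delta_2)$ bivariate normal with correlation
`effect_corr_shared`.  A replication cohort redraws all noise with
$\delta_1$ scaled by `rep_scale`; replication rows randomly list alleles in
swapped order (with the sign flipped) to exercise harmonization.

Defaults, chosen once as a realistic desk-scale study: 500 blocks × 10
variants (5,000 variants) spaced 1 Mb on one chromosome; within-block
$r^2 = 0.5$ (strong enough that pruning at 0.2 keeps one variant per block
and clumping at 0.1 groups block-mates); class probabilities
0.85/0.05/0.05/0.05; effect SD 4 per trait (detectable but not
deterministic at this multiplicity); shared-effect correlation 0.8;
`rep_scale` 0.5 (the replication cohort is materially smaller than
discovery); effect sizes scaled to log-odds via
$se = 1/\sqrt{2\,n_{\mathrm{eff}}\,f(1-f)}$ with a dummy allele frequency
$f = 0.3$ and $n_{\mathrm{eff}} = 4000$.  What the generator does **not**
model: genotype-level sampling, realistic allele-frequency spectra,
population stratification, case-control ascertainment, or LD beyond the
exchangeable block form.  Passing tests therefore demonstrate correctness
and calibration of the estimator and pipeline under the stated dependence
structure, not performance on any particular real cohort.

`truth_metrics` scores a discovered locus as a true positive iff its span
overlaps a block whose target class is target-only or shared; FDP is
counted over loci, while power counts distinct recovered causal blocks so
it cannot exceed 1.

## Known limitations

* The raw counting estimator is slightly anti-conservative in finite
  samples: variants contribute to their own joint counts, so rectangles
  where null p-values happen to cluster get deflated estimates and select
  themselves.  In four-groups simulations at the default conditions the
  realized FDR at a 5% cFDR threshold runs near 8–9% (the suite measures
  and asserts this property honestly; BH on the same data is calibrated at
  ≈4%).  Leave-one-out counting or kernel-smoothed variants would remove
  the bias at the cost of abandoning the exactly-testable counting form.
* Locus-level FDP is higher than variant-level FDP: an isolated lucky null
  variant forms its own (false) locus while true blocks collapse into one.
* The two-level lead-variant scheme some annotation servers apply
  ($r^2$ 0.6 within 0.1) is not implemented; clumping uses the single 0.1
  threshold.
* Conjunctional FDR (association with both traits) and covariate-weighted
  FDR variants are out of scope.

## Problem sizes used by the test suite

Deterministic fixtures are exact and instantaneous.  Monte-Carlo checks
use: null calibration — 20 replicates of 20,000 variants with 50 pruning
iterations; FDP under pleiotropy — 50 replicates of 5,000 variants;
discovery gain — 20 end-to-end replicates of 5,000 variants with strong
shared effects ($\pi_{\text{shared}} = 0.1$, effect SD 5).  The full suite
completes in well under a minute on one CPU.
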