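# Methods

## Data model

The unit of analysis is a *site*: one nucleotide on one strand of one
reference sequence (transcript or chromosome — the pipeline treats the
identifier opaquely), for one modification code (`a` = m6A, `m` = m5C,
`17596` = inosine, `17802` = pseudouridine). For each site and sample the
input is the pair (modified reads, canonical reads) from an 18-column
modkit-style bedMethyl file; coordinates are BED 0-based half-open and
every record spans exactly one base. Counts are the primary data: the
file's percent column is re-derived from the counts whenever count columns
are present, and is only used (with a logged warning) to reconstruct
counts in truncated 11-column files. A site absent from a sample is
treated as (0, 0) — zero coverage, not missing at random.

Records on the "−" strand are accepted and kept distinct in the site key,
never merged with "+" records; transcriptome-aligned reads are expected on
"+".

## Filtering against the IVT control

IVT RNA is synthesised from cDNA and carries no modifications, so IVT
"modification" signal measures the caller's false-positive behaviour at
that site. The filter keeps a site iff

* mean total reads across native replicates ≥ `min_mean_reads` (default 20),
* native modified proportion ≥ `min_native_prop` (default 0.05), and
* IVT modified proportion < `max_ivt_prop` (default 0.05), when the site
  is observed in any IVT sample.

Boundary semantics are deliberate: inclusive (≥) for the native rules,
strict (<) for the IVT rule. Proportions are pooled (Σ modified / Σ total)
by default because pooling is depth-weighted and stable at low coverage;
an unweighted per-replicate mean is available (`prop_mode="mean"`) for
sensitivity analysis. Sites never observed in IVT pass the IVT rule —
an unobserved site cannot be tested against the control — and a strict
mode can additionally require a minimum IVT coverage before the rule is
trusted. IVT summaries pool across cell lines by default, treating the
IVT set as a global modification-free reference. Filter accounting
attributes each failing site to the first failing rule in the order
coverage → native proportion → IVT proportion, so the report's counts sum
to the input count.

Eligibility (coverage and native proportion) is re-applied within each
cell line at testing time: a site must clear the thresholds within a line
to be tested there, while the discovery-level filter is computed over all
native samples.

## Per-site model

Within one cell line, modification counts are modelled by a logit-link
binomial GLM with an intercept and a high-condition indicator. The fit is
iteratively reweighted least squares with convergence at a maximum
coefficient change below 1e-10 (cap 100 iterations); because the design
has two groups, the MLE coincides with the pooled 2×2-table log-odds and
its standard error, which the test suite uses as an independent oracle.
Significance is a two-sided Wald test on β₁ — chosen over a likelihood
ratio because the meta-analysis consumes (estimate, SE) pairs, matching
inverse-variance weighting. Quasi-complete separation (any pooled margin
zero) is flagged non-estimable and excluded downstream; no Haldane or
Firth correction is applied, since a corrected estimate would still not
carry a meaningful finite SE into the meta-analysis. A condition with zero
total coverage makes the site untestable in that line. Dispersion is fixed
at 1 (binomial); residual overdispersion is partially absorbed by the
downstream heterogeneity filter.

Influence diagnostics use the classical GLM recipe at convergence:
leverage hᵢ from the weighted hat matrix, Pearson residual rᵢ, Cook's
distance Dᵢ = rᵢ² hᵢ / (p (1 − hᵢ)²) with p = 2 coefficients, and a
P-value from the upper tail of F(p, n − p) where n counts the line's
covered samples. If the minimum Cook's P across samples falls below
`alpha_influence` (default 0.05), the whole site is pruned from the
meta-analysis (the record is kept and flagged — pruning removes the site,
not the offending sample). With n ≤ p the F distribution is undefined and
the site is un-prunable, with a warning.

## Meta-analysis, heterogeneity, FDR

Per-line effects are pooled by the inverse-variance fixed-effects model.
Cochran's Q is referred to χ²(k − 1); sites with Q P-value below
`alpha_het` (default 0.05) and k ≥ 2 are flagged heterogeneous and
excluded *before* BH correction, so they do not count toward the number of
tests. Sites tested in only one line enter the same BH pool as one-study
metas (k = 1, Q = 0, p_Q = 1) by default — this maximises usable output —
and `--both-lines-only` restricts to sites tested in at least two lines.
BH runs within each modification code (matching per-modification
reporting); a global scope is available. A site is a DMS when its q-value
is below `q_threshold` (default 0.05).

## Adaptive shrinkage

Meta effects are shrunk under the model betahat_j ~ N(beta_j, se_j²),
beta_j ~ Σ_k π_k N(0, σ_k²), with σ₀ = 0 a point mass at zero (exact
normal likelihood N(betahat; 0, se²)) and a geometric grid of ratio √2
from min(se)/10 up to 2·√max(betahat² − se², 0) (fallback 8·min(se)/10
when no effect exceeds its noise). Weights are fit by EM maximising the
log-likelihood plus (λ − 1)·log π₀ with λ = 10 by default, a conservative
nudge toward the null; λ = 1 disables it. The objective is concave in π
for a fixed grid, so the optimum is unique; the implementation verifies
monotone ascent and stops when the penalized log-likelihood improves by
less than 1e-7 (cap 5000 iterations; near-boundary solutions may hit the
cap with π already stable to ~1e-8, which is flagged but harmless). The
reported quantity is the posterior mean Σ_k γ_jk · betahat_j ·
σ_k²/(σ_k² + se_j²) — a multiplicative pull toward zero, so |PM| ≤
|betahat| always. No posterior SDs or local false-sign rates are computed:
shrinkage here serves effect-size ranking and visualisation, and FDR
control remains BH's job.

Shrinkage is fit per modification code on the (β_meta, SE_meta) pairs.
When the package reports that shrinkage "reduces RMSE", the comparison is
over *all* meta-analyzed sites: the large null majority is shrunk to near
zero, which dominates total error; on the true-effect subset alone the
bias-variance trade can go either way.

## Enrichment

A gene is a success for a modification if it carries at least one DMS.
The universe is the set of genes with at least one *tested* site for that
modification — not all annotated genes — because only tested genes could
have been successes. The P-value is the exact upper tail P(X ≥ overlap) of
the hypergeometric distribution, computed with integer combinatorics
(`math.comb`) so small cases agree with exhaustive enumeration to the last
bit; BH correction is applied jointly across all (modification × gene set)
tests. Gene sets and the transcript→gene map are plain TSVs supplied by
the user.

## Stimulation index

The GSIS index is mean(high)/mean(low) secreted insulin. The 95% CI uses
Fieller's theorem for a ratio of independent normal means with
vH = s²H/nH, vL = s²L/nL and pooled df = nH + nL − 2 (Welch df available);
when x̄L² ≤ t² vL the confidence set is unbounded and flagged rather than
reported as a finite interval. The P-value against index = 1 uses the
equivalence (for positive means) with mean equality: a two-sample t
statistic (x̄H − x̄L)/√(vH + vL) on the same df. Everything is scale
invariant, as a ratio must be.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, at
the scale of the motivating design:

| parameter | default | meaning |
|---|---|---|
| cell_lines | {lineA: 3, lineB: 4} | replicates per condition per line |
| depth_mean / depth_dispersion | 60 / 5 | NegBin per-sample coverage (None = constant depth) |
| baseline_prop | Beta(2, 8) truncated ≥ 0.05 | modified proportion of real sites |
| frac_dms / effect_size | 0.1 / 1.5 | share of sites with a ±1.5 log-odds condition effect |
| frac_line_heterogeneous | 0.02 | sites with independently drawn per-line effects |
| frac_ivt_artifact | 0.05 | false-positive sites; artifact proportion ~ Beta(2, 8) used in both native and IVT |
| error_floor | Beta(1, 99) truncated < 0.0125 | IVT miscall rate of clean sites |
| ivt_replicates_per_line | 2 | IVT control samples per line |
| outlier_rate / outlier_replicates | 0 / None | condition-swapped replicates (stochastic or explicit) |

Negative-binomial coverage mimics nanopore per-site depth overdispersion.
Artifact sites use their artifact proportion in both native conditions
(with no condition effect) and in IVT — a persistent basecaller confusion
looks "modified" everywhere. The clean-site error floor is truncated at a
quarter of the IVT threshold: basecaller miscalls at clean sites are rare
and, by design of the 5% filter margin, bounded away from it — without the
truncation a fraction of "clean" sites would carry true IVT proportions
above 5% and be (correctly) removed, making "clean" and "artifact"
undefined. Heterogeneous sites draw per-line effects independently, so
they may be differential in one line and null or opposite in the other;
the pipeline is expected to exclude them via Cochran's Q, and evaluation
excludes them from power denominators. Outlier replicates swap the two
conditions' success probabilities in both of the replicate's samples.

All randomness flows through a single `numpy.random.default_rng` (PCG64)
stream, so outputs are byte-identical for a given seed and numpy major
version.

What the generator does *not* emulate: positional correlation along
transcripts, shared reads across neighbouring sites (counts are drawn
independently per site), transcript-abundance-driven coverage, basecaller
error correlation between native and IVT libraries, and k-mer sequence
context. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated sampling model, not robustness to
every artifact of real nanopore data.

## Problem sizes and evaluation choices

The packaged checks run at sizes chosen to make Monte-Carlo bands tight
while keeping the suite quick: 5,000 sites for null calibration (the
Wald/meta rejection rate at α = 0.05 is required to land in [0.035,
0.065]), ten simulations of 2,000 sites at coverage 100 for FDR/power/
effect-recovery, 4,000 sites for artifact removal, 2,000 replicate draws
for Fieller coverage, and 1,000 random tables for the IRLS-vs-closed-form
oracle at 1e-8. The influence-diagnostic check runs at constant coverage
100 because the "swapped replicate has maximal Cook's distance" guarantee
is a statement about sites actually covered at that depth; under NegBin
coverage the same check holds conditionally on the outlier samples being
well covered.

## Known limitations

* The per-site model has no covariates beyond condition and no
  random-effect or GEE variant; between-line variation is handled by
  meta-analysis and the Q filter, not modelled.
* Separated sites (common at extreme proportions with low depth) are
  dropped rather than stabilised, which loses a small amount of power at
  boundary sites.
* Fixed-effects pooling assumes a common true effect; with many lines a
  random-effects model would be preferable, but the design targets two.
* BH controls FDR under positive dependence; nearby sites on the same
  transcript share reads in real data, which the independence-sampling
  generator cannot probe.
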