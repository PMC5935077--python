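# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## The experimental design the package assumes

A reciprocal transplant over `S` sites: replicate cores from every origin
site are planted at every destination site (origin = destination cores are
*replanted controls*), and fresh *pristine controls* are collected per site
at the end of the experiment. The packaged default is the five-marsh US East
Coast design: 5 × 5 × 3 factorial cores + 15 pristine cores, with two
unrecovered cores modelled as design drops (88 samples). Sample classes are
`transplant`, `replant_control`, `pristine_control`; controls always have
origin = destination.

## Processing conventions

- **Rarefaction** draws each sample's reads without replacement
  (multivariate hypergeometric) to a fixed depth, so all downstream
  dissimilarities compare equal-depth samples. Samples below the depth are
  an error, or dropped under a flag. Deterministic given a seed.
- **Singleton** means grand total = 1 *after* rarefaction; the order is
  rarefy → remove singletons → everything else.
- **Prevalence curation** keeps OTUs present in strictly more than a
  fraction `f` of samples; the integer threshold is the smallest `k` with
  `k/n > f` (for 88 samples at `f = 0.95` that is 84).
- **Per-sample share** (the scan's response) is computed on the rarefied,
  singleton-free table *before* prevalence filtering, as
  `count(otu, s) / Σ_s' count(otu, s')`; it is a proportion in [0, 1] and
  percent is presentation only.
- Ties (e.g. at the top-*N* boundary) break lexicographically on OTU id and
  are logged.

## Distance matrices

Bray–Curtis is computed on counts (post-rarefaction, equal depths) or
relative abundances. Geographic distance is great-circle on a 6371 km
sphere — the analysis only needs rank-consistent distances, and haversine is
standard and reproducible. Environmental difference matrices are absolute
pairwise differences in the variable's own units. A natural-log transform
(off-diagonal only, optional pseudocount) is available for the
control-vs-geographic-distance analysis; the environmental pairwise panel
defaults to untransformed matrices, which on the packaged site table also
reproduces the expected strong temperature/geodistance and nitrogen/carbon
correlations more faithfully than the transformed variant.

## Mantel tests and nMDS

The Mantel statistic is the Pearson correlation of strictly-upper-triangle
entries; significance comes from jointly permuting one matrix's labels with
`p = (1 + #extreme) / (1 + n_permutations)`, one-sided (greater) by default
with a two-sided option, 999 permutations by default, exhaustive enumeration
available for n ≤ 7. Matrix regression is OLS on the same upper-triangle
pairs, so its R² equals the squared Mantel statistic identically.

Non-metric MDS minimises Kruskal stress-1,
`sqrt(Σ(d̂ − δ)² / Σ δ²)`, where δ are configuration distances and d̂ their
isotonic regression (PAVA) onto the rank order of the input
dissimilarities, with primary tie handling (no monotonicity constraint
inside tie blocks). Optimisation alternates isotonic fits with Guttman
transforms; a bisection backtracking step guarantees stress never increases
within a start. The best of `n_starts` random initial configurations plus
one classical-scaling start is returned, column-centred and rescaled to the
input RMS (stress-1 is invariant to scale, rotation and reflection).
*Known behaviour:* on data whose within-cluster distances are all smaller
than all between-cluster distances, nonmetric MDS can satisfy the rank order
with near-collapsed clusters and stress near zero — the classic degeneracy
of ordinal scaling. Strongly structured synthetic data does exactly this;
real communities, with overlapping distance distributions, give the familiar
moderate stress values.

## The indicator-OTU scan

For each prevalent OTU and each variable in
{air temperature, % nitrogen, salinity, geographic distance} (% carbon is
excluded as collinear with nitrogen), every included sample contributes one
point: `x = ln v_destination − ln v_origin` (antisymmetric, 0 for controls)
and `y` = the sample's share of the OTU's grand total. Geographic distance
has no direction and no logarithm at zero, so it enters as `ln(1 + d_km)`
(raw distance available by flag). All sample classes are included by
default, controls at `x = 0`, matching a prevalence universe defined over
all samples. The fit is ordinary least squares with a two-sided t-test of
slope = 0 on n − 2 degrees of freedom; a perfect fit reports p = 0 with a
degeneracy flag. Family-wise error is controlled by Bonferroni:
`α / (n_surviving_OTUs × n_variables)` with α = 0.001. The correction based
on the pre-curation OTU count is reported alongside, since either convention
may be wanted when comparing against historical analyses.

**Caveat — confounding by origin structure.** When communities differ
systematically by origin site, an OTU that merely tracks its origin
correlates with every directional delta (x contains −ln v_origin), so a
significant slope is *not* by itself evidence of an environmental response.
In structured simulations such origin-tracking OTUs reach R² ≈ 0.2–0.4.
This is a property of the design, not a software defect; the calibration
suite therefore evaluates error control on an exchangeable background (see
below), and results on structured data should be read with this in mind.
Relatedly, because the environmental variables are themselves collinear
across sites, a genuine responder to one variable usually also passes on a
correlated variable — the scan reports all passing pairs and leaves the
attribution to the analyst.

## Outcome classification

Pristine controls define each site's reference cloud (replants can be
pooled in by flag). With `d_o`/`d_d` the mean Bray–Curtis from a transplant
to the origin/destination clouds, `baseline_s` the mean pairwise distance
within site s's cloud, and `separation` the mean distance between the two
clouds, the call is:

- `no_change` if `d_o ≤ τ·baseline_origin` and `d_o ≤ d_d`;
- `total_adoption` if `d_d ≤ τ·baseline_destination` and `d_d < d_o`;
- `host_shift` otherwise when `max(d_o, d_d) ≤ separation`;
- `random_shift` otherwise.

The four verbal outcomes are qualitative in origin; this rule is the
package's formalisation. τ = 1.5 by default (a tolerance band of one and a
half times the control dispersion); all constants are configuration, not
code.

## The synthetic-community generator

The generator targets the statistical structure the analysis assumes,
nothing more (no growth dynamics, no seasonality, no spatial structure
within a site):

- Per-OTU baseline weights: one log-normal draw (μ = 0, σ = 1.5 — a
  realistically long-tailed rank-abundance curve for a few hundred OTUs).
- Region structure: each region multiplies all its sites' weights by one
  shared log-normal perturbation (σ = 1.0); each site adds a smaller one of
  its own (σ = 0.3). The site-level term is needed so that the two sites of
  a region are distinguishable — without it a π = 0 transplant is
  equidistant from its origin and destination control clouds and the
  classifier's origin/destination comparison degenerates to a coin flip.
- Expected sample profile: `(1−π)·θ_origin + π·θ_destination` with invasion
  fraction π (default 0.05: low invasion, the regime the transplant
  literature reports); controls are pure origin.
- Planted indicators: selected OTUs are pinned to a flat cross-site
  baseline (default 1% relative abundance) and exempted from region/site
  perturbations, then scaled by `exp(β·Δv)` before renormalisation —
  multiplicative on the simplex, matching the scan's log-linear detection
  model, and antisymmetric under direction reversal.
- Counts: Dirichlet-multinomial, `p ~ Dirichlet(c·θ)`,
  `counts ~ Multinomial(D, p)` with depth D = 5000 and concentration
  c = 5000 (replicate cores overdisperse relative to multinomial; c is
  exposed and `c → ∞` recovers multinomial noise).
- Default planted responses (β = ±1.0 for temperature, ±0.45 for nitrogen,
  −0.37 for salinity) were calibrated once so that the planted regressions
  have expected R² ≈ 0.5 under the calibration conditions below — the
  middle of the range real indicator taxa show — and are not tuned per run.

Two stock configurations ship: `default_config()` (region-structured, 88
samples, low invasion — the study-like conditions used for ordination and
outcome checks) and `scan_calibration_config()` (region/site effects off,
full 90-sample design — an exchangeable background on which the regression
null is exactly true for non-planted OTUs, so false-positive and
family-wise-error properties are well defined).

What passing tests on synthetic data do **not** show: robustness to
compositional artefacts of real sequencing (primer bias, chimeras), to
unbalanced depths before rarefaction, to taxonomic mis-clustering, or to
environmental variables measured with error. The generator draws true
proportions and adds only sampling and replicate noise.

## Problem sizes and numerical choices

Simulated checks use 300 OTUs × 88–90 samples at depth 5,000, 20 seeds per
property — sizes at which every distributional property asserted is stable
while a full test run stays fast. Isotonic regression uses scipy's PAVA;
regression p-values come from the Student-t survival function (regularised
incomplete beta). Matrix symmetry tolerance is 1e-9; simplex checks 1e-12.
Degenerate inputs (all-equal configurations, zero-variance predictors,
all-zero samples) raise errors naming the offending object rather than
propagating NaNs.

## Limitations

- The scan is mass-univariate OLS on proportions; no compositional
  transform, no multivariate or regularised alternative, and Bonferroni
  only (an intentionally conservative choice).
- The outcome classifier needs ≥ 2 controls per referenced site and makes
  no significance statement — it is a descriptive partition of distance
  space.
- nMDS stress comparisons across datasets are only meaningful for similar
  n; and see the degeneracy note above.
- Geographic distance assumes a spherical Earth; fine at the scale of
  hundreds of kilometres.
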