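# Methods

## The analysis in one paragraph

`mlcnet` implements a multi-level correlation-network analysis of a clinical
cohort: a subjects-by-variables table, where each variable belongs to one of
four measurement levels (clinical, lung function, bone marrow, circulating
blood), is turned into a graph whose nodes are variables and whose edges are
statistically significant Spearman correlations (two-tailed p < 0.01,
strict). Edges keep the signed rank correlation rho and are weighted by
|rho|. The network's "isolated modules" are its connected components of size
at least two; "interconnectedness" is quantified as density (realized edges
over all K(K−1)/2 pairs, isolated nodes included); hubs are the
highest-degree nodes. Group-wise networks (e.g. disease vs controls, or
threshold-defined patient subgroups) are compared on density, edge overlap
and hub agreement, with an equal-n subsampling consensus to remove the
sample-size confound.

## Correlation engine

Spearman rho is computed on midranks with pairwise-complete deletion: each
pair of variables uses exactly the subjects jointly non-missing for that
pair, and the pairwise n is stored on the result so every edge is
auditable. Pairwise (rather than listwise) deletion maximizes the usable n
per edge; under missingness completely at random it is unbiased.

Two-tailed p-values use three regimes:

* **exact** (n ≤ 9, no ties): full enumeration of the n! rank permutations.
  The null distribution of rho is computed once per n and cached; the
  p-value counts permutations with |rho| at least the observed value (with a
  1e-12 float-safety margin). Verified in tests against an independent
  pure-Python enumerator and, during development, against R's
  `cor.test(..., method="spearman", exact=TRUE)`.
* **Monte-Carlo permutation** (n ≤ 9 with ties): 20,000 seeded permutation
  draws with the add-one estimator, flagged `mc_permutation`. Exact
  enumeration under ties would require a per-tie-pattern distribution; the
  seeded Monte-Carlo fallback keeps results deterministic.
* **t approximation** (n > 9): t = rho·sqrt((n−2)/(1−rho²)) on n−2 degrees
  of freedom. Midranks make the statistic tie-corrected. Calibration was
  checked by simulation: at n = 200 and threshold 0.01 the realized null
  edge rate is 0.0100 ± 0.0001.

Pairs with fewer than `min_n` (default 5) complete observations, or with a
constant vector after deletion, are *invalid*: they carry a reason string
and can never form an edge, regardless of any stored p. This prevents
sparse variables from fabricating edges.

## Network construction

An edge requires a valid pair with p strictly below the threshold (default
0.01, the conventional signal/noise choice for this family of analyses;
0.05 and 0.001 are exposed for sensitivity). Strictness makes boundary
cases deterministic. All variables entering the analysis are kept as nodes;
isolated nodes matter for the density denominator and for reporting which
variables entered, and exports list them (GraphML/SIF) even though network
drawings conventionally hide them. Thresholds nest: the edge set at t1 is a
subset of the edge set at t2 whenever t1 ≤ t2, so density is monotone in
the threshold — this is asserted as a test invariant.

Exports: GraphML (attribute-preserving, round-trips through the package's
own reader), SIF (sign as the interaction label `pos`/`neg`; isolated nodes
on their own lines), and a CSV edge table — all Cytoscape-importable.

## Modules, hubs, comparisons

A module is a connected component with ≥ 2 nodes. This is an
operationalization: in the source style of analysis, modules are shaded by
an investigator, but non-overlapping "isolated sub-networks" coincide with
components. Modules are named after the level held by a strict majority of
member nodes ("mixed" otherwise) and ordered by descending size then name,
so output is deterministic. Hub ranking is by degree with alphabetical
tie-break — a total order. Network comparisons report both densities, their
difference, the Jaccard index of the edge sets induced on the shared
variables (1.0 when both induced edge sets are empty), and the overlap of
the two top-k degree rankings. No community detection or non-degree
centrality is used; the analysis this package reproduces uses none.

## Group comparisons

Per variable, groups are tested with ANOVA / Kruskal-Wallis (3+ groups) or
Welch t-test / Mann-Whitney U (2 groups). The parametric branch requires
every group to pass Shapiro-Wilk at 0.05 *and* have n ≥ 5 — the
conventional gate at these sample sizes; the policy can be forced with
`parametric="always"/"never"`. Welch's correction is deliberate because the
group sizes are unbalanced (10 vs 35 in the default design). Summaries are
mean ± SD on the parametric branch and median [IQR] otherwise. Raw
two-tailed p-values are flagged at alpha = 0.05 with **no multiple-testing
correction across variables**, matching the presentation style this
pipeline reproduces; the report carries an explicit note. Variables with
fewer than 3 non-missing values in any group, or constant everywhere, are
reported untestable with a reason — never silently dropped. The reported
Mann-Whitney statistic is the U of the first group in sorted-label order.

## Equal-n subsampling consensus

At a fixed threshold, a larger cohort yields a denser network purely
because power grows with n. The control: draw B subgroups of m subjects
without replacement (defaults m = 25, B = 1000), compute the full
correlation matrix per draw, and average rho and p element-wise over the
draws where the pair was valid; the consensus network thresholds the mean
p. Averaging raw p-values is reproduced deliberately as specified by the
procedure this package implements; a mean of p-values is not itself a
calibrated p-value, so the consensus network is a stability summary, not an
inference. Documented alternatives: Fisher-z averaging of rho, and an
edge-frequency rule (edge kept when present in ≥ 50% of valid replicates).
A pair valid in fewer than half the replicates is invalid overall.

One structural consequence, visible in simulation: when one cohort has
exactly m subjects, its "subsamples" are all the full cohort, while the
larger cohort's averaged p is attenuated by Jensen's inequality around the
detection threshold. The equalized gap under a shared generating process is
therefore near, but not exactly, zero. The bias-removal check accounts for
this by testing the gap against its own simulated no-difference envelope
(95% interval from an independent calibration batch) rather than against a
hard zero; coverage is required up to the same 3-standard-error Monte-Carlo
allowance used by the other calibration checks.

## Stratification

Group rules merge a label set into one stratum and compare it with the
complement (e.g. merged smoker + never-smoker controls, n = 25, vs COPD,
n = 35). Cut rules dichotomize on a variable with the upper stratum closed
(value ≥ cut), following the "< 60 or ≥ 60" convention of the contrasts
this reproduces (DLCO 60% ref; 300 eosinophils/µL; 45 pack-years). Subjects
missing the cut variable are excluded and counted, not imputed. Strata keep
the pooled variable roster; stratum-wise unusable pairs are carried as
invalid.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes — it
stands in for clinical data that is not publicly available, so its defaults
*are* the study conditions: 60 subjects in three groups (15 never-smokers,
10 smokers, 35 COPD), 47 variables over the four levels, 5% missingness
completely at random, heavy-tailed marginals (t with 8 df).

Data come from a latent Gaussian copula: per group, latent variables are
multivariate normal with pairwise correlation `target_rho` inside each
active planted block and 0 elsewhere (the combined matrix is validated
positive semi-definite before sampling, so incompatible overlapping blocks
fail loudly). Each column then passes through a strictly increasing
marginal transform, which leaves every rank statistic untouched; the
population Spearman correlation of a planted pair is (6/π)·arcsin(ρ/2),
cross-checked by Monte-Carlo in the tests. Count-kind variables are floored
to integers, giving realistic ties at a small cost in attenuation.

The default blocks mirror the module structure the analysis is meant to
resolve: an 11-variable bone-marrow cellularity block, a 7-variable
circulating-count block, and a 2-variable macrophage block in every group,
plus disease-specific structure — a 12-variable lung-function/repair block,
negative eosinophil–FEV1 and eosinophil–DLCO links, a CD34
progenitor/immunity block, and a smoking-driven inflammation block — so the
COPD group's latent network is strictly denser than the never-smokers'.
Block correlations (0.45–0.7) were chosen as realistic moderate-to-strong
clinical correlations compatible with joint positive semi-definiteness.

What the generator does **not** emulate: group differences in means or
scales (marginals are identical across groups, so bivariate Table-style
contrasts are null by construction), informative missingness, measurement
error structure, and the actual marginal shapes of clinical assays. Passing
recovery tests therefore demonstrates correct rank-scale network inference,
not robustness to those real-data features.

## Problem sizes used in checks

Monte-Carlo sizes were chosen to put estimator noise well below the
tolerances being asserted: exact-p equivalence over 500 random vectors
(n ≤ 8); null edge-rate calibration over 500 cohorts of n = 200 × 30
variables (3-SE band around 0.01); planted recovery over 200 cohorts at
n = 35 and latent rho 0.8, with the sensitivity bound 0.95 fixed in advance
from a brute-force power simulation of the same operating point (power
≈ 0.999); subsampling control over 2 × 120 cohort pairs at m = 25, B = 200;
type-I calibration over 1000 replicates; module-oracle agreement over all
edge subsets on 4 nodes plus 10,000 random graphs on ≤ 8 nodes. The
acceptance script re-runs the same computations at comparable sizes
(B = 200 subsampling, 60 + 60 pairs) with seeds derived from `--seed`.

## Numerical choices

* Rho is clipped to [−1, 1] and snapped to ±1 within 1e-12, so perfect
  monotone pairs report exactly ±1.
* Permutation counts use a 1e-12 margin when comparing |rho| values, making
  exact p-values immune to float representation of tied extremes.
* Complete-data matrices above the exact-p regime use a vectorized path
  (column ranks, one correlation matrix product); it is asserted equal to
  the per-pair path to 1e-12.
* All randomness flows through `numpy.random.default_rng` seeds carried in
  specs and configs; the pipeline manifest records sha256 checksums of
  every output, and rerunning a config with the same seed reproduces them
  bit-for-bit.

## Known limitations

* Edge p-values are not corrected for the K(K−1)/2 comparisons; the 0.01
  threshold is the analysis's own signal/noise control, and densities are
  only comparable at a fixed threshold and roster.
* "Resilience" has no formula here; fragmentation proxies (module count,
  largest-component fraction, density) are explicitly labelled proxies.
* The consensus of averaged p-values inherits the calibration caveat above.
* Exact p-values with ties fall back to Monte-Carlo; at n ≤ 9 with heavy
  ties the p has ~1/sqrt(20,000) relative noise.
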