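# Methods

## Model and null hypothesis

The enrichment test treats a differential gene expression signature as a
fixed multiset of G pairs (r_g, s_g): the rank of |z_g| (ascending, average
rank on ties) and the sign of z_g, with sign(0) = 0.  The null hypothesis
for a gene set is maximum-entropy: each member independently occupies one
of the G signature entries with probability 1/G, *with replacement*.  All
null moments used by the test are exact finite-sample consequences of this
model and the realized signature:

* E[rs] = m_rs, E[r] = m_r, E[r²] = m_r2, E[r²s] = m_r2s — the empirical
  means over the G entries.  They are always computed from the realized
  (r, s) vectors, so ties are handled exactly; the no-tie closed forms
  m_r = (G+1)/2 and m_r2 = (2G² + 3G + 1)/6 serve only as test oracles.
* Per-member null variance of the directed summand is AW²AM²(m_r2 − m_rs²),
  of the undirected summand AW²(1 − |AM|)²(m_r2 − m_r²), and their
  covariance AW²·AM·(1 − |AM|)(m_r2s − m_rs·m_r).

The test suite verifies these against exhaustive enumeration of all G^N
placements for small G and N to 1e−12, which pins the with-replacement
convention (a permutation-without-replacement null would have different
moments).

Asymptotic normality of the standardized scores rests on the Lindeberg
condition, which holds when no single member dominates a null variance
branch.  `lindeberg_diagnostic` reports the largest per-member share of
either branch; the pipeline aggregates a warning when any regulon exceeds
the (configurable) 0.10 threshold.  The warning is informational: random
gene sets with uniform association modes routinely have one member near
10–20% of the small undirected branch, and the calibration tests show the
normal approximation still holds well at sizes ≥ 30.  The default
`min_size = 30` reflects the same concern — below it the normal
calibration of NES is not guaranteed (Berry–Esseen) — and can be relaxed
or made strict.

## Tie-breaking and degenerate cases

* p+ = p− exactly: the sign of the final NES is taken from the directed
  branch (NDES), which carries the directional evidence.
* A branch with zero null variance (all AM = 0 kills the directed branch;
  all |AM| = 1 kills the undirected one) is dropped, and significance
  reduces to the two-sided normal test of the surviving standardized
  score.  This fallback is logged rather than raised, since equal-weight
  literature gene sets (AW = AM = 1) are a legitimate input.
* Tail probabilities are computed in log space (`norm.logsf` /
  `ndtri_exp`), the final p is clamped to the open interval (0, 1) at
  machine precision, and |NES| is clamped at the normal quantile of the
  smallest positive double (≈ 38.5), so extreme enrichments never produce
  infinities or exact zeros.

## Effect size (PES)

PES divides the observed NES by the most extreme NES attainable by
re-placing the members on *distinct* signature entries (a real gene set
occupies distinct genes; this deliberately differs from the
with-replacement null).  Because NES+ and −NES− are linear in the placed
(r, r·s) values with fixed per-member coefficients, and within each sign
class of the signature a position's value to any member is a fixed
coefficient times its rank, the search reduces to a rearrangement
problem: members are processed in decreasing coefficient magnitude and
greedily take the best remaining end of the rank-sorted sign classes.
The greedy optimum is recomputed through the full scoring pipeline (the
null moments do not depend on placement, so only the raw scores change).
This construction is exactly optimal for homogeneous association modes
(verified against brute force in the tests); for strongly mixed modes it
is a principled upper-bound heuristic, and PES is clamped to [−1, 1].
The bootstrap confidence interval resamples members with replacement and
uses a normal-theory interval on the Fisher-z scale, which respects the
bounded range.

## Leading edge

A member's leading-edge score is (1 − |AM|)r + AM·rs for positive
enrichment (minus the second term for negative), i.e. its realized
contribution pattern with unit weight; AW is deliberately excluded so
that post hoc member selection is not biased by a priori importance.  Its
p-value is the fraction of signature positions scoring at least as high
under the same member-specific weighting, hence always ≥ 1/G, with BH
adjustment (Bonferroni available) across the regulon.

## Differential signatures

`mwu_signature` computes per-gene z = (U − n₁n₂/2)/σ_U from the
Mann–Whitney statistic with the tie-corrected normal approximation and no
continuity correction (verified against scipy per gene).  Exact
enumeration is unnecessary at signature scale, and the normal
approximation keeps the z-values antisymmetric under swapping the
phenotypes.  Genes constant across all samples get z = 0 with a warning.

## Network inference

* **Estimator.**  Mutual information is estimated on copula-transformed
  data (rank/(n+1)) by recursive quadrant partitioning: a cell splits at
  its midpoint while a chi-squared uniformity statistic over the four
  quadrant counts exceeds the 0.05 critical value (df 3) and the cell
  holds ≥ 8 points.  The root cell is always split once, which makes the
  estimate a continuous random variable under independence (no atom at
  zero) and so supports the percentile-based null model; deeper splits are
  purely data-driven.  Leaf contributions use the marginal-count
  correction.  Both knobs (significance level, minimum occupancy) are
  exposed.  MI is reported in nats and clamped at 0.
* **Null model.**  MI draws from shuffled copula marginals form the null;
  the empirical survival function is used up to the 95th percentile, and
  beyond it the log10 tail probability is linear in MI with a Theil–Sen
  (median-based) slope, anchored at the junction's empirical tail
  probability so the p-value is continuous and nonincreasing by
  construction.  Because the MI estimator is discrete-valued at small n,
  the junction probability is near, not exactly, 0.05.  The default
  1,000,000 null pairs matches the recommended production setting; the
  tests and the acceptance run use 10,000, which is ample for the tail
  fit at the sample sizes involved.
* **Per-network pruning.**  Each subnetwork uses round(n(1 − 1/e))
  profiles sampled without replacement (the decorrelation of a bootstrap
  without its duplicated points), Benjamini–Hochberg across all
  regulator–target p-values at the requested FDR (per subnetwork), then
  one deterministic DPI pass on the undirected skeleton: the minimum-MI
  edge of every three-gene clique is marked (ties: all marked) and all
  marked edges removed at once, making the operation idempotent.
* **Consensus.**  Subnetworks accumulate until a maximum count or until
  every regulator has a minimum number of unique targets; final MI and
  Spearman correlations come from the full matrix.  Regulon weights are
  the copula transform of the (count, MI) ordering; modes are the
  Spearman correlations.

## Synthetic data

The generators define the study conditions for every calibration claim:

* Null signatures: i.i.d. standard normal z over G genes (G = 19,350 for
  the at-scale calibration, matching the target universe size).
* Random ("null-model") gene sets: uniformly drawn members, sizes uniform
  in [50, 300], copula-uniform weights, modes uniform in [−1, 1]; 2491
  sets in the at-scale run.  Swap mode replaces a template's members with
  a same-size draw from the complement, keeping its weights and modes
  (how weights should be reassigned after a swap is not prescribed
  anywhere, so the template's values are carried over).
* Totally-null gene sets: members drawn only from genes with two-sided
  Mann–Whitney p > 0.50 in a two-phenotype comparison (40 vs 40 samples
  over 19,350 genes, half the genes shifted by ±2 — strong enough that
  the differential half is unambiguous and the eligible pool is purely
  central).  A signature-only fallback (|z| below the median) exists as a
  documented stand-in when no expression matrices are available.
* Programmed enrichment: each member's z is shifted by
  effect·AW·sign(AM), acting on the signature directly rather than
  re-simulating expression; this keeps power curves fast and isolates the
  mode-consistent extreme-mass mechanism the test is designed to detect.
* Expression matrices: latent standard-normal activity per regulator and
  sample; the regulator transcript reports its activity with small noise
  (sd 0.1); targets are direction·strength·activity + noise·ε with
  strength uniform in [0.6, 1.0] and noise sd 0.5 by default (a
  signal-to-noise regime where strong edges are clearly detectable at
  ~130 subsampled profiles); decoys are pure noise; everything is mapped
  through exp() to non-negative abundances, a monotone map that leaves
  all rank-based analyses unchanged.

What these emulate — and what they do not: independence of null genes,
uniform member placement, known regulator→target monotone dependencies.
They do not emulate count noise (negative binomial dispersion), library
size artifacts, gene–gene correlation beyond the programmed edges, or
composition effects; passing calibration here shows the statistics behave
as derived under their own assumptions, not that real data meet those
assumptions.

## Validation analyses

* Agreement tables: expected counts from the independence model
  row·col/N; per-cell departures use the adjusted standardized residual
  (O − E)/√(E(1 − row/N)(1 − col/N)) with two-sided normal p-values,
  Bonferroni ×9; overall chi-squared with 4 dof; Kendall's tau-b on both
  axes ordered DOWN < NS < UP with tie correction.  The published per-cell
  Z values are not reproducible from the printed counts by either the raw
  or the adjusted residual formula, so only expected counts, tau-b, and
  the chi-squared p-value are asserted.  The tau-b confidence interval
  uses the tie-corrected null-variance normal approximation; published
  intervals likely used a different (consistent-estimator) variance and
  are not asserted.
* Calibration suite: raw fraction p < 0.05, counts significant after BH
  and Bonferroni, and one-sample KS statistics of NES against N(0, 1) and
  of p against Uniform(0, 1).  The acceptance run disables the effect-size
  computation since rates depend only on p-values.
* Clopper–Pearson (exact) binomial intervals for all reported
  proportions.
* Permutation-null diagnostics: pooled samples are relabeled preserving
  group sizes; each null signature's Spearman correlation with the
  original signature is recorded with the permutation's phenotype
  imbalance, reproducing the mechanism by which phenotype-permutation
  null models become contaminated when a real difference exists.

## Problem sizes

Defaults in the test-suite and acceptance runs: enumeration oracles at
G ≤ 6, N ≤ 3; Monte-Carlo standardization checks at 10⁵ placements; null
normality at 10⁴ gene sets of size 50 on a 2000-gene signature; at-scale
calibration at 2491 sets on 19,350 genes; network recovery at
20 regulators × 10 targets + 500 decoys with 200 samples and a
10,000-pair MI null; DPI Markov-chain checks over 40 seeds at n = 200.
These sizes give standard errors comfortably below the asserted
tolerances while completing in minutes on a single core.

## Known limitations

* The PES extremal placement is a greedy optimum; for adversarial mixes
  of positive and negative modes it can be marginally suboptimal, which
  the clamp to [−1, 1] absorbs.
* The analytical null is asymptotic in regulon size; very small or
  heavily imbalanced gene sets (one dominant weight) can have miscalibrated
  tails — the size guard and the dominance diagnostic exist to flag this.
* The MI null model assumes all pairs share the sample count used to fit
  it; fitting is per subsample size, and a model fitted at one n should
  not be reused at a different n.
* Consensus inference computes regulator–target pairs only; DPI therefore
  sees triangles only through shared regulators, as in the standard
  regulator-centric formulation.
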