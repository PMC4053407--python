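# Methods

This note documents the models, estimators and numerical choices behind
`sociokin`, what the synthetic-data generator does and does not emulate,
and the limitations a user should keep in mind.

## Association detection and the half-weight index

A *sampling period* is one calendar day by default
(`sampling_period_days`), mirroring field schedules in which a study
area is surveyed once per day. Two individuals are associated within a
period if any pair of their fixes lies within the simultaneity window
(`simultaneity_window_h`, default 1 h) and the distance threshold
(`association_distance_m`, default 350 m). The distance threshold is
deliberately generous relative to typical group spread because
triangulated locations carry positional error of order 100–200 m;
coordinates are treated as exact point estimates and the error is
absorbed by the threshold rather than propagated.

Association strength is the half-weight index
`HWI = x / (x + y_ab + 0.5 (y_a + y_b))`, with `x` the number of periods
the dyad was associated, `y_ab` periods both were identified but not
associated, and `y_a`, `y_b` periods one was identified without the
other. The half-weight denominator down-weights periods in which a dyad
is more likely to be recorded apart than together, the usual situation
with incomplete telemetry coverage. Two documented conventions are
fixed here: "both identified" requires location on the same calendar
day (any times), and dyads never co-identified are included as HWI = 0
in population summaries, so the number of dyads is always `C(n, 2)`.

## Preferred-companion permutation test

Daily *groups* are the connected components of the day's association
graph (the chain rule). The null model permutes the group-by-individual
incidence structure by sequential swaps: pick a day with at least two
groups, pick two groups, and exchange one member of each. Each swap
preserves exactly the day's group-size multiset and every individual's
number of identified days, so the null holds gregariousness and
sampling effort fixed while destroying dyadic preference. After a
burn-in of 1000 accepted swaps, one null dataset is scored every
`flips_per_perm` (default 100) accepted swaps, `n_perm` (default 1000)
times. The chain is a random walk with a symmetric proposal on the
constrained state space, so its stationary distribution is uniform over
reachable configurations.

Directional p-values follow the preferred-companionship logic: a real
society shows a *higher* CV and mean non-zero HWI, and a *lower* mean
and proportion of non-zero dyads, than its null. All p-values use the
add-one convention `(1 + hits)/(1 + n_perm)`, so "p < 0.001" at 1000
permutations corresponds to 1/1001. Calibration: under a
random-grouping null the CV test rejects at 0.05 with empirical rate
≈ 0.03–0.05 (it is slightly conservative at short chains; burn-in
matters more than thinning).

## Social units by modularity

Weighted Newman modularity is
`Q = (1/2W) Σ_ij (A_ij − s_i s_j / 2W) δ(c_i, c_j)` with node strengths
`s_i` (sum of HWI, not binary degree) and zero diagonal. Networks with
at most `exhaustive_max_n` nodes (default 10) are solved exactly by
enumerating all set partitions (restricted growth strings). Larger
networks use recursive leading-eigenvector bisection of the generalized
modularity matrix, followed by single-node polishing, pairwise-merge
moves, and Kernighan–Lin passes (tentative locked moves with
best-prefix revert), restarted from spectral, greedy-agglomerative,
all-singleton, all-in-one and two-eigenvector sign-pattern seeds. On
random weighted graphs with n ≤ 8 this heuristic attained the
enumerated optimum in 800/800 tested instances. Determinism: nodes are
processed in sorted-label order, eigenvector signs are fixed, ties are
broken towards fewer units then lexicographic labels, and unit numbers
follow first occurrence in sorted-id order, so the output is invariant
to input row order. No HWI thresholding is applied before clustering.

Observed mean unit size is corrected for incomplete marking as
`mean / mark_rate`; with only a fraction of a unit tagged, the observed
size underestimates the true size by exactly that fraction in
expectation.

## Genetics

Pairwise relatedness is the Queller–Goodnight estimator: for x = (a, b)
and y = (c, d) at a locus,
`num = 0.5 (δ_ac + δ_ad + δ_bc + δ_bd) − p_a − p_b` and
`den = 1 + δ_ab − p_a − p_b`; numerators and denominators are summed
over loci typed in both individuals, the directional estimate is the
ratio of sums, and the symmetric value is the mean of the two
directions (`combine="ratio-of-sums"` pools both directions instead).
Allele frequencies include the focal pair by default, matching common
software; the leave-two-out variant is available
(`frequencies="exclude-pair"`). Expected values are 0.5 for
first-degree kin and 0 for unrelated pairs *when frequencies are
estimated from a large, predominantly unrelated sample*; in a small
kin-structured sample the estimates are compressed downwards, which is
inherent to the estimator, not a defect — analyses should estimate
frequencies on the widest available sample. Dyads sharing no typed
locus are NaN (never coerced to 0); dyads sharing fewer than 8 loci are
flagged low-confidence.

Diversity per locus: `Na` (distinct alleles), `He = 1 − Σ p_i²`, `Ho`
(fraction heterozygous among typed), and allelic richness by
rarefaction to `n` gene copies,
`Σ_i [1 − C(N − N_i, n) / C(N, n)]`, with `n` defaulting to the
smallest per-locus sample. The Hardy–Weinberg exact test shuffles the
locus's gene copies into random diploid pairings (Monte-Carlo
realisation of the exact conditional null) and scores arrangements by
conditional probability (`2^h / Π n_g!` up to constants); one-sided
heterozygote-deficit/excess variants are exposed. Under simulated
equilibrium (50 diploids, 4 equifrequent alleles) the test rejects at
0.05 with empirical rate ≈ 0.05–0.06. Multiple testing across loci uses
the Holm step-down ("sequential Bonferroni") rule.

## Kernel utilization distributions and overlap

The UD is a fixed bivariate-normal kernel estimate with the bandwidth
as the kernel standard deviation on both axes (default 250 m),
evaluated on a `grid_cells × grid_cells` lattice (default 200,
interpreted as cells per axis). All individuals share one extent — the
pooled bounding box of retained fixes expanded by three bandwidths — so
the volume of intersection `VI = Σ_cells min(UD_a, UD_b)` is well
defined; mismatched grids are an error, never resampled. Individuals
with fewer than five fixes are excluded. VI is symmetric, 1 for
identical UDs, 0 for disjoint ones, and decreases monotonically as two
ranges move apart.

## Mantel, partial Mantel, within/between tests

The Mantel statistic is the Pearson correlation over off-diagonal
dyads; significance comes from jointly permuting rows and columns of
one matrix (10 000 permutations by default; exact enumeration available
for n ≤ 8). The partial Mantel correlates the residuals of x on z and
y on z and permutes the residual matrix (the raw-permutation variant is
exposed). The within/between test compares mean dyadic values inside
versus across social units by permuting unit labels over individuals,
with optional dyad-class filters (e.g. adult-female pairs) from a
metadata table. Two-sided p-values are the default; one-sided
alternatives are exposed. Calibration at n = 15 individuals: empirical
type-I rates ≈ 0.04–0.06 for Mantel and ≈ 0.04 for partial Mantel under
a confound-only null (x and y each driven by z with no direct link).
Caveat: when a *discrete* confounder (unit co-membership) drives both
matrices and the control matrix is only a noisy continuous proxy for
it, linear residualisation removes the confounding incompletely and the
partial correlation retains a positive bias — visible in the synthetic
pipeline when matrilineal units are both the kin and the spatial
structure. The package's space-only null scenario therefore decouples
kinship from units (`kin_structure=False`).

## Lagged association rates and social models

The LAR is the probability that a dyad associated on day t is
associated again at lag τ:
`g(τ) = Σ a_ij(t) a_ij(t+τ) / Σ a_ij(t)·1[i, j both identified at t+τ]`,
summed over ordered day pairs and dyads. This dyadic-conditional
denominator makes g directly comparable with the null association rate
(`mean of n_i(t)/(N(t) − 1)`, the chance a specific partner would be an
associate under random mixing) and with the social-model component
proportions. An alternative denominator weighting by the number of
associates at t+τ is available (`denominator="associates"`).

Lags are binned logarithmically (10 bins per decade). Uncertainty per
bin and per fitted parameter is a delete-one-block jackknife over
10-day periods, `SE² = (G−1)/G Σ (θ_(i) − θ̄)²`.

The candidate family is `g(τ) = c_cc + Σ_k c_k exp(−τ/T_k)` with zero,
one or a constant component and one or two casual components, each
either pinned (`Σ c = 1`) or free (the deficit `1 − Σ c` is the rapid-
disassociation fraction): eight models. Numerical choices: durations
are fitted on the log scale with bounds [10⁻², 10⁶] days and four
deterministic starts; proportions are bounded to [0, 1] with a penalty
on `Σ c > 1`; bins are weighted by inverse jackknife variance, with the
SE-vs-lag profile smoothed by a quadratic in log lag so that a bin's
weight does not depend on its own realised noise (raw denominator
counts are *not* usable as weights — day pairs within a bin re-use the
same association bouts, overstating precision by orders of magnitude);
the fitted lag range is capped at half the study span, since longer
lags rest on very few effective replicates; the overdispersion factor
for qAICc, `ĉ`, is the weighted residual sum of squares of the most
general candidate divided by its residual degrees of freedom, floored
at 1; and `qAICc = dev/ĉ + 2K + 2K(K+1)/(n−K−1)` with K counting all
fitted parameters including the rapid-disassociation freedom.
Components are reported sorted by duration (constant first), and the
percentages in reports are the fitted `c_k` themselves with
`1 − Σ c_k` as the rapid fraction — this package's documented reading
of how fitted constants map to "proportions of associations".

## The synthetic-data generator

`gen_population` builds matrilineal units: one founder female per unit,
further members drawn as offspring of unit females (hidden, unsampled
sires; one or two mates per mother), so units contain mother–offspring,
full-sib, half-sib and avuncular dyads; adult males are unaffiliated.
Genotypes descend Mendelianly from founder draws on per-locus frequency
tables (uniform over 3–15 alleles by default) with ~5.4% of cells
masked as missing. The pedigree-expected relatedness matrix (additive
relationship, tabular method) is the oracle against which the
genotype-based estimator is validated. `kin_structure=False` keeps the
same social geometry but makes everyone an unrelated founder.

`gen_movement` is a two-level Gaussian model: unit centroids follow a
*mean-reverting* AR(1) around fixed home centres (stationary sd 800 m,
day-to-day autocorrelation 0.9) — mean reversion, rather than a pure
random walk, keeps home ranges stationary so kernel UDs and unit
separation are meaningful over a season; members scatter around the
centroid (sd 100 m by default), with offspring displacements correlated
with their mother's by `kin_preference` (0 by default; positive values
make associations relatedness-graded beyond shared space); solitary
males range independently and more widely. Each individual is observed
on a day with probability `fixes_per_month / 30` (default 7/30), with
unit-mates observed near a shared survey time with probability 0.9 so
co-observed unit-mates fall inside the 1-h window. Home centres sit on
a jittered grid (spacing 3 km), guaranteeing spatial separation of
units. None of this models habitat, resources, dispersal or demography;
passing tests demonstrate that the estimators recover the structure
*this* model generates, not that real populations are this clean —
real telemetry has localisation error, irregular effort and range
shifts that the generator deliberately omits.

`gen_association_series` simulates dyad-level association streams
without the geometric layer, so temporal model recovery can be tested
in isolation. Mixture proportions are proportions of
*association instances* (matching how component percentages are
reported), not of dyads. Dyads are disjoint pairs: constant dyads are
associated on every co-sampled day; casual dyads associate in bouts
whose start times form a Poisson process (mean gap defaulting to 10×
the casual duration — long relative to a bout, yet several bouts per
study) and whose durations are exponential, which makes the dyadic LAR
decay exactly exponentially by memorylessness; rapid dyads associate on
isolated single days (rate 0.05/day, never two consecutive). Because
integer dyad counts can only approximate the requested mixture, the
class rates are recalibrated after allocation so the *expected*
model-recoverable proportions (including the small re-association
persistence of casual and rapid dyads, which otherwise leaks into the
constant term) equal the requested values exactly. Both members are
sampled each day with probability 0.9.

## Reproducibility

All stochastic procedures take explicit integer seeds and use numpy's
PCG64 generator; a missing seed in the simulators is an error, not a
silent default. Pipeline runs with the same inputs, configuration and
seed produce byte-identical outputs (covered by a test).

## Known limitations

- Relatedness estimates within small kin-structured samples are
  downward-biased by sample allele frequencies (see above).
- The partial Mantel control is linear; discrete confounders are
  removed incompletely.
- Jackknife SEs for strongly non-linear fit parameters (casual
  durations) tend to be generous, while those for proportions are close
  to nominal — roughly 68% one-SE coverage, as expected of a calibrated
  standard error.
- The permutation-test chain shares one state across samples; p-values
  are slightly conservative for very short chains.
- Problem sizes in the test-suite simulations (tens of individuals,
  hundreds of days, hundreds of permutation replicates) are chosen to
  exercise every estimator at realistic field scales while keeping the
  whole suite in the minutes range on one CPU.
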