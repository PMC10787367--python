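# Methods

This note documents the statistical models behind each pipeline stage,
the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical conventions that
affect results.

## Study design assumed by the pipeline

The pipeline targets a longitudinal intervention design: calves
randomized to three arms — control (CON), rumen microbiota
transplantation (RMT), and autoclaved rumen fluid transplantation
(RFT) — with stool metagenomes, blood metabolomes, and phenotypes
collected at days 15, 35, and 56 after birth, twelve animals per arm.
Each (group, day) cell is a *subgroup*. Missing samples are tolerated
throughout: every per-subgroup statistic uses that subgroup's own n,
and sample alignment takes the intersection of table and metadata
columns with a logged warning for anything dropped.

## Feature tables and prevalence filtering

Species tables follow the MetaPhlAn merged-abundance dialect (lineage
strings are reduced to the terminal clade); pathway tables are plain
feature × sample counts. The prevalence filter keeps features present
(value > 0) in **strictly more than** a given fraction of samples
(default 10%); a feature at exactly the threshold is removed. Relative
abundances are converted to predicted read counts by multiplying each
sample's abundances by its total sequence count, rounding
half-to-even (deterministic and unbiased; the expected rounding error
per cell is below 1/total_reads).

## SparCC basis correlations

Observed relative abundances are compositional: the unit-sum
constraint induces spurious negative correlations. SparCC estimates
correlations between the latent *basis* abundances from the log-ratio
variance matrix t_ij = var(log x_i/x_j), which satisfies
t_ij = ω_i + ω_j − 2ρ_ij √(ω_i ω_j) for basis log-variances ω and
basis correlations ρ. Under sparsity (most ρ ≈ 0) the ω solve the
linear system Σ_j t_ij ≈ (D−2)ω_i + Σ_k ω_k; ρ follows by inversion
and is clipped to [−1, 1].

Numerical conventions:

- **Dirichlet resampling.** Per inner iteration, fractions are drawn
  per sample from the Dirichlet(counts + 1) posterior; the final
  estimate is the component-wise **median** over 20 iterations
  (mean available). A deterministic point-estimate mode
  (fractions = (counts+1)/total) exists for debugging and fast tests.
- **Exclusion.** Up to 10 rounds remove the currently strongest pair
  with |r| > 0.1 from the variance system (the pair's t entry leaves
  the row sums and the system matrix loses the corresponding
  coefficients). Exclusion stops early when no pair exceeds the
  threshold or a feature would retain fewer than three partners.
- **Degeneracy.** A feature whose solved basis variance is
  nonpositive has its correlations set to missing and is reported
  with a warning.
- **Significance.** Each of 100 permutations shuffles every feature's
  counts across samples independently (destroying between-feature
  dependence, preserving marginals) and reruns the estimator. The
  two-sided p is (1 + #{|r_perm| ≥ |r_obs|})/(1 + 100), so the
  smallest attainable p is 1/101 ≈ 0.0099: an edge passes the
  P < 0.01 rule only by exceeding every permuted value.
- **Seeding.** One integer seed drives independent substreams for the
  observed-data Dirichlet draws and each permutation, making the whole
  inference bit-reproducible.

## Cross-subgroup edge heterogeneity (Cochran Q)

Each subgroup is treated as one study. Per edge, correlations are
Fisher-z transformed, z = atanh(r) with r clipped to ±0.999 and
variance v = 1/(n−3) — the standard correlation meta-analysis model.
With weights w = 1/v and pooled effect θ̄ = Σwz/Σw, Q = Σw(z−θ̄)² is
referred to the upper chi-square tail with k−1 degrees of freedom.
Subgroups with n ≤ 3 (undefined z variance) are dropped; fewer than
two usable subgroups yields a missing result. The edge family for BH
adjustment (FDR 0.05) is the union of edges significant in at least
one subgroup of the comparison at hand, with effect sizes filled from
every subgroup's full r matrix. Only the fixed-effect Q test is
implemented; no τ² random-effects estimation.

## Group-specific edges and hubs

For heterogeneous edges (FDR < 0.05) the IQR fence rule assigns an
edge to a single subgroup: quartiles of the k effect sizes are
computed by linear interpolation between order statistics (type 7 —
the convention matters at k = 3, where Q1 and Q3 are the midpoints of
adjacent order statistics), and the candidate outliers are the minimum
if it falls strictly below Q1 − 0.75·IQR and the maximum if strictly
above Q3 + 0.75·IQR. The edge is called specific only when exactly one
candidate exists and the extreme value is unique. The rule operates on
raw r (an equivalent z-scale variant would change the fences; raw r is
the scale on which the effect sizes are defined). Specificity can be
assessed across groups within a day or across days within a group.

A power caveat worth knowing: at k = 3 the high-fence condition is
algebraically (max − mid) > 3·(mid − min). With per-subgroup
correlation estimates at n = 50 (sampling sd ≈ 0.14), the two
non-planted groups spread too far to satisfy this in roughly 15–20% of
replicates even for planted gaps near 0.9, so per-replicate detection
plateaus around 80–85%; misassignment to a wrong group is essentially
never observed.

Hub scores of each group-specific subnetwork are Kleinberg scores: for
an undirected graph, the principal eigenvector of the |r|-weighted
adjacency matrix, computed per connected component and normalized so
the component maximum is 1; nodes above 0.5 are hubs. Scores are
invariant to edge ordering and uniform weight scaling.

## Differential features

Microbial tables are CLR transformed per sample
(log(x+ε) − mean log(x+ε), default ε = half the smallest nonzero
value) and then inverse-rank transformed per feature
(Φ⁻¹((rank−0.5)/n), average ranks for ties; Blom's offset available).
Phenotypes are tested untransformed. The tie-corrected Kruskal–Wallis
H tests days within each group (or groups within each day), with BH
adjustment per family across features; all-constant input returns
H = 0, p = 1. Dunn's pairwise z uses the tie-corrected pooled rank
variance and is reported unadjusted — the family-level decision rests
on the Kruskal FDR. Because Kruskal is rank-based, the inverse-rank
step cannot change its p value (asserted in the test suite); it
matters only for procedures sensitive to the numeric scale. The
repeated measurements of one calf across days are treated as
independent strata by the time-axis test; this ignores within-animal
correlation and is a known caveat of the stratified rank approach.
Diarrhea-style incidence contrasts use the conditional 2×2 Fisher
exact test (a Monte Carlo chi-square variant covers r×c tables);
two-group continuous contrasts use the Wilcoxon rank-sum test, exact
for small tie-free samples.

## Delta associations

Changes are computed within calf between day pairs (15→35, 15→56),
only for calves observed at both days: microbial deltas on the CLR
scale, metabolite deltas on log intensities, phenotype deltas raw.
(Spearman is invariant to monotone per-feature transforms but CLR is a
per-sample operation, so the microbial scale choice is substantive and
configurable.) Every microbial-feature × trait pair is screened with
Spearman correlation on the shared calves (≥ 5 required); for n ≤ 9
without ties the two-sided p is exact, from the full n! permutation
null, otherwise the t approximation is used. The screening rule flags
|ρ| > 0.7 **and** p < 0.01 (setting `--r-min 0` recovers the pure
p-rule). An association is specific to a focal group (default RMT)
when it is significant there and every other group is either
non-significant or significant with the opposite sign; missing group
estimates count as non-significant.

## Mediation

Triads (microbial delta T, metabolite delta M, phenotype delta Y) are
admitted when the microbe passed the delta screen against both traits
and the M–Y Spearman p is below 0.01. Each triad is analysed with the
quasi-Bayesian Monte Carlo estimator for linear, no-interaction
models:

    M = α₁ + aT + ε_M        Y = α₂ + cT + bM + ε_Y

Both models are fit by OLS; 1,000 parameter vectors are drawn from
each fit's asymptotic multivariate normal; per draw ACME = a·b,
ADE = c, total = ACME + ADE (exact per draw). Point estimates are draw
means; the ACME p value is the two-sided Monte Carlo sign test
2·min(#pos, #neg)/n_sims floored at 2/n_sims. At least 6 complete
triples are required and the treatment must vary. No multiplicity
adjustment is applied to mediation p values by default (a BH option
exists); no sensitivity analysis for sequential ignorability is
provided. Note that when the mediator noise is small relative to a·T,
T and M are nearly collinear in the outcome model and the ACME becomes
poorly identified — wide intervals there are a property of the data,
not the estimator.

## Synthetic data generator

`simulate_counts` draws, per subgroup, latent log-basis abundances
from a multivariate normal whose correlation matrix carries the
planted structure (shared pairs, group-specific pairs, per-day mean
drifts for differential features), exponentiates to basis abundances,
normalizes to fractions, and samples counts multinomially at a
Poisson-distributed depth (default mean 100,000 reads). This
log-normal-basis + multinomial-read model is exactly the generative
assumption under which SparCC is consistent, which is what makes
recovery tests on these data meaningful. Planted matrices that are not
positive definite are repaired by eigenvalue clipping with a warning.
`simulate_traits` realizes each mediation chain on the delta scale
(metabolite delta = a·CLR-delta + noise; phenotype delta = c·delta +
b·metabolite-delta + noise) on top of random per-calf baselines;
unchained traits are independent noise. Default trait noise is 1.0 —
about one CLR unit of microbial change — because a much smaller value
makes treatment and mediator collinear and the planted ACME
unidentifiable in any analysis. Ground truth (per-group basis
matrices, differential features, specific edges, chain coefficients)
is serialized as JSON next to the tables.

What the generator does **not** emulate: phylogenetic structure and
realistic taxon abundance distributions (means are log-normal i.i.d.),
sequencing error and mapping noise, zero inflation beyond what
multinomial sampling induces, within-calf autocorrelation of traits
across days, and chains sharing a trait (a later chain overwrites an
earlier one's contribution to a shared trait). Passing recovery tests
therefore demonstrates correctness of the estimators under their own
model assumptions, not robustness to every property of real
metagenomic data.

## Problem sizes used in verification

The test suite and `scripts/acceptance.py` use desk-scale versions of
the design: 20–30 features, subgroups of 12–100 samples, 100
permutations, 20 replicate simulations for recovery rates, 500
simulated edges for Q-test calibration, 1,000 pairs for the delta
screen null, 200 replicates for mediation type-I error, and a full
six-stage CLI pipeline (20 features, 12 calves per group, 3 days)
executed twice to confirm byte-identical output under a fixed seed.
These sizes keep every stage's statistical behavior measurable while
the whole verification completes in a few minutes on one CPU.
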