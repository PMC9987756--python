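# Methods

This note records the models, conventions and numerical choices behind
`kogatype`, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Community typing

**Distance.** Profiles are compared by the Jensen–Shannon distance
√JSD with natural logarithms, a metric bounded by √ln 2 ≈ 0.8326.
Zeros are handled by adding a pseudocount (default 1e-9) to every entry
and re-normalizing before the divergence is evaluated; at that magnitude
the perturbation of any distance is far below 1e-4 and no result in the
package depends on the exact value. The prevalence filter (keep genera
with mean relative abundance strictly above 0.01%, unweighted mean over
the samples of the table passed in) runs before distances; the removed
mass is *not* redistributed, mirroring the common practice of clustering
the filtered profiles as-is. The filter's scope is the caller's choice:
the nested gut step can either reuse a globally filtered table (default)
or re-filter within each oral-type subgroup (`refilter_subgroups`).

**PAM.** k-medoids via the classical deterministic BUILD + SWAP: BUILD
greedily adds the medoid with the largest reduction in total
nearest-medoid distance; SWAP repeatedly applies the single best
strictly-improving medoid/non-medoid exchange; all ties break toward the
lowest sample index, so the output is a pure function of the distance
matrix (no restarts, no RNG). Like every single-exchange local search —
including the canonical R `cluster::pam` — this can terminate in a
1-swap local optimum that is not the global medoid-set optimum; on tiny
random instances (n ≤ 7) this happens for roughly 3–8% of instances.
For the well-separated community structures the typing pipeline targets
this has never been observed to change a chosen clustering, but it is a
real property of the algorithm, not of this implementation.

**Choosing k.** The Calinski–Harabasz index is generalized to distance
matrices through medoids: W = Σ d(x, medoid(x))², B = Σ n_c ·
d(medoid_c, global medoid)² with the global medoid minimizing the total
squared distance, CH = (B/(k−1))/(W/(n−k)). k scans 2..10 and the argmax
wins (ties → smallest k); W = 0 returns +∞ so identical-point clusters
dominate. Mean silhouette width (singletons scoring 0) is recorded per k
as a robustness check but does not influence the choice.

**Cluster labels.** A cluster's label is the taxon maximizing
(mean abundance inside − mean abundance outside); ties break
alphabetically. The difference rule is deliberate: a globally abundant
genus (Streptococcus in saliva) would otherwise also label the cluster
it is *depleted* in. A plain inside-mean rule is available
(`dominant_rule="inside"`). Composite oral–gut labels concatenate the
dominant-genus initials (SB, SP, HB, HP).

**Tests of separation.** PERMANOVA uses sums of squared distances
(SS_total = Σ_{i<j} d²/n, SS_within per group analogously) and the
permutation p-value (#{F_perm ≥ F_obs}+1)/(n_perm+1) under seeded label
shuffling; the pseudo-F agrees with scikit-bio's implementation to
1e-9. Per-taxon group comparisons use the two-sided Mann–Whitney U with
normal approximation, tie and continuity correction; an all-tied taxon
is defined to give U = nm/2, p = 1. Raw p-values are reported with
significance stars and no multiplicity adjustment. PCoA is classical
scaling; axis signs are fixed so each axis's largest-magnitude
coordinate is positive, which makes ordinations reproducible. Whether
the ordination uses √JSD or JSD affects only the picture, never the
cluster labels; √JSD (the clustering metric) is used.

## SparCC networks

Defaults follow the standard formulation: per inner iteration, fractions
are drawn from Dirichlet(counts+1) per sample; T_ij = Var log(f_i/f_j)
(n−1 denominator); basis variances solve the linear system with D−2+1
structure (diagonal D−1, off-diagonal 1, right side row sums of T);
ρ_ij = (ω_i+ω_j−T_ij)/(2√(ω_iω_j)) clipped to [−1,1]; the single
strongest pair with |ρ| above the exclusion threshold (0.1) is removed
from the system and the basis re-solved, up to 10 rounds; 20 inner
iterations are aggregated by the element-wise median. Negative solved
variances are floored at 1e-12 before the square root. At least 4 taxa
are required (the basis system is otherwise degenerate) and all-zero
taxa are rejected by name rather than dropped.

Permutation p-values shuffle each taxon's counts across samples
independently — destroying all between-taxon association while
preserving marginals — and recompute SparCC with the inner iteration
count reduced to 5 for tractability (both counts configurable);
p = (#{|R_perm| ≥ |R_obs|}+1)/(n_perm+1), two-sided. The default
n_perm = 100 resolves the conventional p < 0.05 cutoff with minimum
attainable p ≈ 0.0099; below 19 permutations a warning is raised.

Estimator calibration, measured in the test suite at D = 50, n = 200,
depth 10⁴: the off-diagonal bias |mean R̂| is ~1e-4; the mean *absolute*
off-diagonal R̂ is ≈ 0.055, indistinguishable from the exact Pearson
correlation of the true latent log-abundances on the same draws — this
is the √(2/(πn)) sampling floor of any correlation estimate at n = 200,
not estimator bias. A planted basis correlation of 0.8 is recovered
within ±0.15, and scaling any sample's counts by a constant moves no
entry by more than ~0.003 (the +1 prior is the only non-invariant
ingredient).

Seeded networks are a pure function of (R, p, cutoffs): level 1 collects
partners of the seed with |R| strictly above 0.3 and p strictly below
0.05, sorted by descending R; level 2 repeats the query from each
level-1 partner excluding only the seed — other level-1 members may
reappear, and level-2 edges are tallied with multiplicity per parent
branch, matching how published two-level tables count them. Exports are
edge-list TSV or GraphML (networkx).

## Health scoring

Given per-type mean relative abundances of the panel species, each
species row is standardized with the n−1 (sample) standard deviation —
the convention confirmed by the bundled reference panel, whose printed
rows have sample sd exactly 1 (e.g. the ±0.5/∓1.5 patterns of species
abundant in a single type). Harmful species are negated *before*
percentile mapping. Percentile = Φ(z)·100 rounded half-away-from-zero to
an integer; rounding before binning is load-bearing: Φ(−0.6902) = 0.24506
rounds to 25 and therefore scores 2, not 1, and without it one oral type
total comes out 33 instead of the reference 34. Quartile bins are
lower-closed, [0,25)→1, [25,50)→2, [50,75)→3, [75,100]→4, with 0 and 100
clamped into the outer bins. A species with identical means in every
type degenerates to z = 0 → percentile 50 → score 3 everywhere, with a
warning. Species in the panel but absent from the data are scored as
all-zero rows with a warning (dropping them would make totals
incomparable across cohorts).

The percentile is the *population* normal CDF of z, not an empirical
rank among the four types — with four values per row an empirical rank
could only take four values and cannot reproduce the reference totals.

## Synthetic cohorts

The generator emulates the post-profiling data the pipeline consumes,
not sequencing: per body site a two-component Dirichlet-multinomial
mixture in which the cluster's dominant genus (Streptococcus/Haemophilus
oral, Bacteroides/Prevotella gut) has its concentration multiplied by a
dominance boost. A subject's gut cluster is drawn conditionally on its
oral cluster via a 2×2 coupling matrix. Defaults: 112 subjects, oral
mixture weights (0.554, 0.446), coupling rows (0.694, 0.306) and
(0.72, 0.28) — so the expected four-type split is ≈38/17/32/13% —
depth 20 000, boost 50.

Concentrations: dominants 2.0, with 73 (oral) / 58 (gut) common genera
decaying geometrically 1.5→0.5. At boost 50 the boosted dominant takes
roughly 60% of the community and the weakest common genus sits near
3×10⁻³, thirty-fold above the prevalence cutoff. The 140 (oral) / 120
(gut) rare genera share a fixed 0.15% sliver of every community,
uniformly Dirichlet-distributed within it, so each rare genus has mean
abundance ≈10⁻⁵ and *cannot* cross the 10⁻⁴ cutoff — by construction the
filter keeps exactly 75 oral and 60 gut genera. (Giving rare taxa tiny
Dirichlet concentrations instead looks natural but is heavy-tailed
enough for single samples to push rare taxa across the cutoff.)
Dispersion values were chosen once for clear but not degenerate type
separation: within-type JSD spread is visible in ordinations, silhouette
at k=2 is ≈0.57, not ≈1.

What passing tests on this generator do **not** show: real salivary
communities have continuous gradients between dominance regimes, nonzero
correlation structure among the non-dominant genera, overdispersion
beyond Dirichlet-multinomial, and batch effects. Recovery of planted
labels (ARI ≈ 1 at boost 50) demonstrates the pipeline's correctness,
not that real cohorts separate this cleanly; on real data the optimal k
and the cluster memberships are empirical findings, not guarantees.

The SparCC generator draws latent log-normal basis abundances with a
prescribed covariance, closes them to fractions and observes multinomial
counts — the model under which SparCC is consistent. The scoring helper
materializes species tables with exact prescribed per-type means so the
scoring chain can be verified end to end without sampling noise.

## Problem sizes used by the test suite

Clustering recovery runs 50 seeded cohorts at the full study scale
(112 subjects, 215/180 genera, depth 20 000) in ≈10 s. SparCC
calibration uses D = 50, n = 200, depth 10⁴. The PERMANOVA type-I check
runs 500 null simulations at n = 30 with 199 permutations each. The PAM
oracle comparison enumerates all medoid sets on 200 instances with
n ≤ 7. These sizes were chosen so the whole suite completes in well
under a minute of compute per stochastic block while keeping
Monte-Carlo error small relative to the asserted tolerances.

## Known limitations

- PAM is a local search; global optimality is not guaranteed (see above).
- SparCC p-values inherit the granularity 1/(n_perm+1); with the default
  100 permutations, multiple-testing control across a large correlation
  matrix is out of scope (the workflow thresholds raw p at 0.05, as is
  conventional for these seeded networks).
- The indicator-species panel is user input; the bundled reference panel
  is shipped as a default, not derived, and the totals carry no clinical
  claim.
- No phylogeny-aware distances (UniFrac) — they require a tree, which
  genus tables do not carry; Bray–Curtis ordination is likewise out of
  scope since typing is defined on JSD.
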