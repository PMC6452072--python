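# Methods

## The model of the landscape

The package treats a landscape survey as a weighted bipartite network whose
lower level is the surveyed **sites** and whose higher level is the
**flower-visitor species**, with the edge weight `A_ij` the total visits of
species `j` recorded at site `i` over all observation rounds.  Aggregating
rounds into a single matrix assumes the within-season interaction structure
is stable enough that one landscape network is the object of interest;
per-round networks are deliberately not retained.  Because all sites host
the same sentinel plant, differences between site nodes reflect habitat
attributes rather than floral context.

Rows or columns whose marginal total is zero are dropped (with a logged
warning) when the matrix is built: specialization, the null models and the
module search are undefined for isolated nodes.

## Specialization d′

For a node with interaction vector `a` (total `K`), partner availabilities
`q_j = L_j / F`:

    d_raw = Σ_j (a_j / K) ln( (a_j / K) / q_j )        [nats; 0·ln 0 := 0]

`d_raw` is standardized by the extremes achievable by integer re-allocations
of `K` across partners:

- **d_max** is computed *exactly* by dynamic programming over allocations
  with per-partner caps `a_j ≤ L_j` (a partner cannot absorb more than its
  observed total).  The objective is separable, so a knapsack-style DP over
  partners × remaining total finds the true maximum in `O(K · F)` — cheap at
  field scale.  A greedy fill of partners in increasing `q_j` order, the
  intuitive alternative, is *not* the maximizer (with availabilities
  `L = (1, 4, 95)` and `K = 4`, greedy attains 3.003 nats against the true
  4-on-one-partner optimum of 3.219), which is why the exact DP is used.
  A `dmax_unconstrained` flag instead places the whole total on the rarest
  partner (`d_max = ln 1/q_min`), for users who prefer the uncapped
  convention; the two agree whenever the rarest partner can absorb the
  node's total.
- **d_min** is the largest-remainder integer allocation proportional to
  `q`.  This is a *baseline*, not the enumerated minimum: it represents
  "interacting in proportion to availability", converges to `d = 0` as
  counts grow, and makes `d′ = 0` mean exactly that.  Since integer
  rounding can leave the observed configuration marginally below the
  baseline, `d_min` is clipped to `min(d_min, d_raw)` so `d′ ∈ [0, 1]`
  always holds.

`d′ = 1` therefore marks a node as specialized as its marginal totals
allow — in particular a site whose visitor species occur nowhere else.
Species-level d′ uses the transposed matrix.

**Node strength** of species `j` is `Σ_i A_ij / K_i`, the summed dependency
of sites on that species; each site's dependencies sum to one, so species
strengths sum to the number of sites (a conservation law asserted in the
tests).

## Modularity and its optimizer

Barber's weighted bipartite modularity of a joint assignment `m` of sites
and species to modules is

    Q = (1/F) Σ_ij [ A_ij − K_i L_j / F ] δ(m_i, m_j),

exactly 0 for the one-module partition and bounded by [−0.5, 1].

The maximizing partition is sought by simulated annealing over assignments,
the same objective that tree-sampling implementations for quantitative
bipartite networks optimize; downstream quantities depend only on the
maximizing partition and its Q, not on the sampler.  Moves are single-node
reassignments to an existing or a fresh module, plus occasional
(probability 0.1) merges of two modules; ΔQ is evaluated in O(1) through
incremental bookkeeping of each node's weight into every module, and the
kernel is JIT-compiled.  Acceptance follows the standard rule (always if
ΔQ ≥ 0, else with probability `exp(ΔQ/T)`) under geometric cooling.

Defaults: `T0 = 0.02`, cooling `0.98` per sweep, `50` moves per node per
sweep, stop after `200` sweeps without improvement (cap 2000 sweeps), and
**4 independent restarts** keeping the best partition.  Two choices here
deserve a note.  First, a slowly-cooled single chain (e.g. cooling 0.995
from `T0 = 0.05`) spends its entire patience budget in the warm phase,
where acceptance is nearly free and the best-seen partition is whatever a
random walk stumbled on; empirically it returns markedly worse Q than a
faster-cooled chain on the same move budget.  The default therefore cools
fast enough to reach `T ≈ |ΔQ|` within the patience window.  Second,
restarts are the cheap insurance against the residual run-to-run spread of
any single chain.  A reduced-budget schedule (`scaled(0.25)`, used for null
ensembles via `fast_null`) shrinks moves per sweep and accelerates cooling
by the same factor rather than truncating patience, so it still anneals to
low temperature.

Ties in Q (within 1e−12) are resolved toward fewer modules; labels are
canonicalized by first appearance over site nodes then species nodes, and
the returned Q is always recomputed from the final partition rather than
trusted from the incremental updates.  A matrix with a single node on
either level gets the one-module partition with Q = 0 and a warning.  The
optimizer is checked against exhaustive partition enumeration on networks
of up to 8 nodes.

The **z-score** of the observed Q against a null ensemble uses the sample
standard deviation; z > 2 is reported as significantly modular.

## Null models

Randomizations preserve, exactly, the row totals, column totals, grand
total and number of nonzero cells of the observed matrix.  Cells are chosen
with probability proportional to `(K_i/F)(L_j/F)` — first accepting cells
that cover a still-empty row or column (at most rows + columns draws), then
filling among remaining empty cells up to the observed link count; one
interaction unit is placed on every chosen cell and the remaining `F −
links` units are placed one at a time with the same probabilities,
rejecting placements that would overshoot a marginal.  When placement
stalls, bounded swap moves (≤ 10·F) rebalance units between rows within a
column; if a draw still cannot satisfy the contract it is regenerated from
scratch (≤ 1000 attempts, after which the error suggests a Patefield-style
fallback).  Every returned draw is verified against the contract.  Note
the popular reference implementation of this scheme preserves marginals
only in expectation; here exact preservation is part of the contract and
of the test suite.

Each of the `n_null` (default 100) draws is run through the module search;
the resulting Q values form the z-score null, and the node-level
participation coefficients and within-module degrees of the null partitions
are **pooled across nodes and replicates per level**.  Critical thresholds
are the empirical `threshold_quantile` of those pooled values — default
0.975, the upper limit of a central 95% interval, computed with type-7
(linear) interpolation; 0.95 is available by configuration.

## Node roles

With `k_it` the node's interaction *weight* into module `t` and
`k_i = Σ_t k_it`:

    c = 1 − Σ_t (k_it / k_i)²      (0 when all partners share one module)
    z = (k_is − mean_s) / sd_s     (own-module weight, standardized over
                                    same-level nodes of module s, sample sd)

Weighted rather than binary quantities are the default, consistent with the
weighted modularity; a `binary` flag reduces both to the classic
degree-based definitions (and the two provably coincide on 0/1 matrices,
which the tests check against a direct binary implementation).  Modules
with a single same-level node or zero spread give `z = 0` rather than NaN,
so classification is total.  Standardization pools same-level nodes only,
the standard convention for bipartite roles.

Roles use strict inequalities against the thresholds: network hub
(`c > c_crit` and `z > z_crit`), between-module connector (`c` only),
within-module hub (`z` only), else peripheral.  Fixed classic thresholds
(c = 0.62, z = 2.5) are available as a preset only; the pipeline derives
thresholds from nulls.

## Linking network position to reproduction

Per-plant reproductive success is standardized for flower availability:
`fert_prop = pods / (unfertilized flowers + pods)`, plus seeds per pod.
Site summaries carry the mean and the sample (n−1) variance of both —
plant-level for `fert_prop`; for seeds both the pooled-pod variance
(default) and the variance of plant means are computed, since the weighting
convention is a modelling choice.

Site-level GLMs of mean fertilized-pod proportion (quasi-binomial, logit)
and mean seeds per pod (quasi-Poisson, log) on `c` and on `d′` are fitted
by IRLS with **prior weights equal to the per-site response variance** —
the convention of weighting averaged responses by their variance is kept
as the default deliberately; the statistically conventional
`inverse_variance` scheme is one configuration flag away, and both weight
schemes are worth reporting when they disagree in sign.  Dispersion is
Pearson χ²/df; standard errors scale with √dispersion and p-values use the
t distribution on residual df.  Point estimates equal the ordinary
likelihood estimates (dispersion affects inference only), which the tests
verify against direct likelihood maximization.  A constant response makes
the IRLS scale degenerate; such fits are returned explicitly flagged with
zero dispersion rather than failing.

Land-use comparisons fit the response on a land-use factor (treatment
coding against the alphabetically first level) with the family appropriate
to the response, and report an overall F test from the dispersion-scaled
deviance difference against intercept-only.

Distance–similarity regressions use great-circle distances (haversine,
Earth radius 6371.0088 km) and the absolute difference of the node metric
per unordered site pair — a *dissimilarity*, so a negative slope means
more-distant sites are more alike.  Pairs share sites and are therefore
not independent; the simple-LM approach is kept on purpose (no Mantel
correction) and every such fit carries a note saying so.

AICc selection compares gaussian single-predictor models plus
intercept-only: `AICc = AIC + 2k(k+1)/(n−k−1)` with `k` counting the
variance parameter (so a one-predictor model has k = 3).  Models with
ΔAICc < 2 are flagged most explanatory; if intercept-only ranks first, no
candidate is considered suitable.

## The synthetic landscape generator

The generator emulates the sampling design the analysis assumes: 20 sites
split 6/5/4/5 over remnant forest, avocado orchard, dairy pasture and
rotational potato cropping; sites placed uniformly in a 40 × 40 km box
with ≥ 1 km pairwise separation; ~57 expected visits per site (a ~1134
visit landscape); 15–18 sentinel plants per site with 20–40 flowers each.
Each land use owns a private species pool (the planted modules) beside a
shared generalist pool; a species is made landscape-wide with probability
`overlap`, and a fraction of private species are specialists restricted to
one site.  Species abundances are lognormal (σ = 0.9: a few common, many
rare species) and visit counts negative binomial (dispersion 1.5), because
field visitation counts are overdispersed — the same reason the analysis
uses quasi-likelihood families.  Insect orders are assigned with a
Diptera-dominated composition; the `study_shaped_preset` sharpens this to
the observed visit shares (~78% Diptera, syrphids ~48% of all visits) and
is a qualitative mimic of scale and composition, not a reconstruction of
any dataset.

Reproduction is generated in a second stage from the *realized* network:
the module search runs on the generated matrix and each site's
participation coefficient enters the per-flower fertilization probability,
`logit p = β0 + β_syr·z(syrphid visits) + β_hym·z(hymenopteran visits) +
β_c·c_site` (defaults −0.5, 0.5, 0.3, 1.0; predictors z-scored across
sites so the β are comparable), with pods binomial per plant and seeds per
pod Poisson with `log mean = γ0 + γ_vis·z(total visits)` (defaults 2.0,
0.15).  Because `c` is measured from the realized network rather than
planted directly, recovery tests exercise the full pipeline.

What the generator does **not** emulate: spatial autocorrelation of
species distributions, the temporal structure of repeated observation
rounds, within-site floral heterogeneity, or detection error.  Passing
recovery tests therefore show the pipeline recovers its own generating
structure under realistic sampling noise — not that field data meet these
assumptions.

### Recovery-test regimes

Planted-module recovery is only a fair test where the planted partition is
identifiable: every pool species must be detectable at its sites, which
with lognormal abundances requires expected per-species visit counts well
above one (the recovery tests use 150 visits/site over 8-species pools).
Species the generator made landscape-wide are excluded from the
planted-versus-recovered comparison since their generating module is no
longer their pool.  Even so, the annealing search routinely finds
partitions with Q at or above the planted partition's Q — genuine finer
structure in the draw — so recovery is asserted as mean normalized mutual
information over replicates, not exact label equality.  Effect-recovery
tests isolate the participation-coefficient effect (β_syr = β_hym = 0,
β_c = 1) so the sign being recovered has a single planted cause.

## Problem sizes and determinism

Everything is deterministic given the seeds: the generator and pipeline
derive independent per-stage streams from one seed, so changing one
stage's workload does not perturb another's draws.  Default test and
example workloads use 20-site landscapes, null ensembles of 8–100
replicates (reduced-budget searches for nulls), 50-replicate calibration
and 100-replicate sign-recovery batches — sizes chosen so the full suite
runs in a few minutes on one CPU while keeping the Monte-Carlo assertions
well away from their thresholds.

## Known limitations

- The annealing search is a heuristic; optimality is only guaranteed where
  exhaustive enumeration can check it (≤ 8 nodes).  Restarts mitigate but
  do not eliminate run-to-run spread on larger networks.
- Exact-marginal null draws are produced by rejection and repair; for
  matrices whose margins admit few integer solutions the generator may
  need many attempts (it reports failure rather than silently relaxing the
  contract).
- The pairwise distance regressions inherit the non-independence of site
  pairs; their p-values are descriptive.
- d′'s `d_min` baseline is the proportional allocation, not the enumerated
  minimum over integer allocations; d′ is therefore 0 for
  proportional-to-availability behaviour by construction.
- Variance weighting (rather than inverse-variance) upweights the
  *noisiest* sites; it is retained as the default for comparability, not
  because it is statistically optimal.
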