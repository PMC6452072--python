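# polliscape

Bipartite **site–pollinator** network analysis for mosaic agricultural
landscapes: from raw flower-visitation records to weighted network metrics,
null-model-calibrated module structure and node roles, and statistical links
between a site's network position and the reproduction of sentinel plants
placed there.

## Who it is for

Pollination and landscape ecologists who survey insect visitation to a
standardized (sentinel) plant across many sites and want to ask: *does the
structure of the landscape-scale visitation network predict pollination
function?*  Instead of the usual plant × pollinator network, the lower level
is the **sites** themselves and the higher level the **flower-visitor
species**, with edge weights equal to total visits.  A site's position in
this network then summarizes the habitat's visitor community.

## What it computes

For a weighted incidence matrix `A` (sites × species) with row totals `K_i`,
column totals `L_j` and grand total `F`:

- **Specialization d′** — the Kullback–Leibler divergence of a node's
  interaction frequencies from partner availability,
  `d = Σ_j p_ij ln(p_ij / q_j)` with `p_ij = A_ij / K_i`, `q_j = L_j / F`,
  standardized to `d′ = (d − d_min) / (d_max − d_min) ∈ [0, 1]` over integer
  re-allocations of the node's total (`d_max` by an exact dynamic program
  with partner-availability caps).  `d′ = 1` marks a site whose visitors
  occur nowhere else.
- **Node strength** — `s_j = Σ_i A_ij / K_i`, the summed dependency of sites
  on species `j`; species strengths add up to the number of sites.
- **Modularity Q** (Barber's weighted bipartite form) —
  `Q = (1/F) Σ_ij [A_ij − K_i L_j / F] δ(m_i, m_j)`, maximized over joint
  site/species module assignments by seeded simulated annealing with
  restarts.
- **Null models** — marginal- and connectance-preserving (vaznull-style)
  randomizations give the Q null distribution (z-score; `z > 2` =
  significantly modular) and per-level critical thresholds for node roles
  (default: 97.5th percentile of pooled null node values).
- **Node roles** — participation coefficient `c = 1 − Σ_t (k_it / k_i)²`
  and within-module degree `z` (weighted), classified into network hubs,
  between-module connectors, within-module hubs and peripheral nodes.
- **Function models** — variance-weighted quasi-binomial / quasi-Poisson
  GLMs of fertilized-pod proportion and seeds per pod on `c` and `d′`;
  land-use comparisons with dispersion-scaled F tests; pairwise
  distance-versus-metric-similarity regressions; AICc model selection with
  an intercept-only suitability guard.
- **Synthetic landscapes** — a generator that plants land-use species pools
  (modules), generalist/specialist visitors and reproduction causally tied
  to visitation and network position, with full ground truth for recovery
  tests.

## Worked example

```bash
python examples/03_modularity_roles.py
```

```
Q = 0.250 with 4 modules
null Q: mean 0.192, sd 0.009 -> z = 6.30 (significantly modular)
critical thresholds for sites: c > 0.74, z > 1.64
critical thresholds for species: c > 0.74, z > 2.71

role counts:
  species module_hub   2
  species peripheral   52
  site    module_hub   1
  site    peripheral   19
```

The synthetic 20-site landscape is significantly more modular than its
marginal-preserving randomizations (z = 6.3 ≫ 2): visits concentrate within
land-use-specific site–species modules.  No node clears both null-derived
thresholds, so the network has no hubs; two species act as within-module
hubs.  `examples/01–04` walk through generation, specialization/strength,
modularity/roles and the reproduction models; each prints what its numbers
mean.

The same pipeline runs from the shell on CSV inputs:

```bash
polliscape simulate --preset study-shaped --seed 1 --out sim/
polliscape analyze sim/visitation.csv --plants sim/plants.csv \
    --out results/ --n-null 100 --seed 1
```

writing `node_metrics.csv`, `partition.csv`, `null_summary.csv`,
`models.csv` and a `run_summary.json` holding the seed, Q, z, thresholds
and role counts.

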