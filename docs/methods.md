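# Methods

This note records the models, conventions and numerical choices implemented
in `ecorestore`, with enough detail to re-derive every quantity the package
computes. It makes no empirical claims beyond what the test suite and
`scripts/acceptance.py` compute.

## Networks and metrics

A network is an unweighted bipartite graph between n plants (rows) and m
pollinators (columns), stored as a binary incidence matrix. Fully
constructed networks may not contain isolated species; intermediate
sub-networks produced during perturbation/restoration may
(`subnetwork(..., allow_isolated=True)`).

Attributes: size S = n + m, asymmetry A = m/n, connectance C = L/(n·m) with
L the number of links, and nestedness NODF.

**NODF.** Rows and columns are sorted by decreasing marginal totals. Every
ordered pair of rows (and of columns) contributes
`100 · |overlap| / MT_lower` if the lower-ranked line has a strictly smaller
and positive marginal total, and 0 otherwise; NODF is the mean over all
n(n−1)/2 + m(m−1)/2 pairs. A strict staircase scores exactly 100; an
identity matrix scores exactly 0 (calibration targets of
`scripts/acceptance.py`). NODF is undefined with fewer than two species on a
side; the package returns 0 with a warning.

**Centralities.** Degree is the raw partner count. Closeness is *harmonic*
closeness on the bipartite graph, chosen because it remains finite and
comparable on the disconnected graphs produced by cascades. Betweenness is
shortest-path betweenness; normalization does not change the induced
ranking.

**Projection and β_eff.** The one-mode projection of a side weights each
pair of same-side species by their number of shared partners. β_eff is the
weighted nearest-neighbor degree of that projection,
β_eff = Σ s_i² / Σ s_i with s_i the weighted degree of species i. A
k-regular projection gives β_eff = k.

## Synthetic generator

`GeneratorConfig(n_plants, m_pollinators, connectance_target,
attachment_bias, seed)` hits the requested link count
L = round(C·n·m) exactly and never produces isolates:

1. a skeleton of max(n, m) links covers every species (random permutation
   pairing, the longer side matched onto the shorter);
2. remaining links are added one at a time with probability proportional to
   `(d_row · d_col)^bias` over the still-absent cells.

Bias 0 gives near-uniform fill; larger bias concentrates links on hubs,
which raises degree heterogeneity and NODF (verified by Monte Carlo in the
test suite). Feasibility requires max(n, m) ≤ L ≤ n·m. The generator does
**not** attempt to reproduce other properties of empirical webs (modularity,
phenology, weighted visit rates); it only spans the (S, A, C, heterogeneity)
space needed by the analyses. The standard suite crosses
S ∈ {40, 60, 80} × A ∈ {1.0, 1.5, 2.5} × C ∈ {0.10, 0.18, 0.26} (27
configurations) with the bias cycling through {0, 1, 2}.

## Dynamical models

### n-D (per-species)

For plant i (pollinators symmetric):

dP_i/dt = P_i·(α_i − Σ_j β_ij P_j + Σ_k γ_ik A_k / (1 + h·Σ_k γ_ik A_k)) + μ

with γ_ik = ε_ik·γ0/D_i^p, where ε is the incidence matrix and D_i the
focal species' degree (the trade-off between interaction strength and
number of partners). Species with zero degree receive zero mutualistic
benefit. Defaults: α = 0.3, β_intra = 1, β_inter = 0.01, h = 0.2, γ0 = 1,
p = 0.5, μ = 10⁻⁴ — standard values in mutualistic-community modelling:
positive intrinsic growth (facultative mutualism), weak interspecific
competition, saturating benefits, and a small immigration term that keeps
reintroduced species from sticking at exactly zero.

### 2-D (per-guild)

One effective abundance per guild with the same functional form; the
network enters through ⟨γ⟩, the **degree-weighted average** of the
per-species aggregate mutualistic strengths (each species' row sum of the γ
matrix, weighted by its degree). Unless β is supplied explicitly, the
effective self-limitation folds the mean interspecific competition a
species feels into the intraspecific term:

β = β_intra + β_inter · (mean side size − 1).

This is a deliberate reduction choice: with β = β_intra alone the 2-D
equilibrium systematically overshoots the n-D species mean by ~11–13% even
on dense homogeneous networks, because each species in the n-D model is
suppressed by its whole guild. With the folded β the 2-D equilibrium agrees
with the n-D species mean to within 0.3% on dense homogeneous test networks
(asserted within 10% in the suite).

### 1-D (whole community)

dx/dt = B + x(1 − x/K)(x/C − 1) + β_eff·x²/(D + (E + H)x)

Defaults B = 0.1, K = 5, C (Allee threshold) = 1, D = 5, E = 0.9, H = 0.1 —
the standard parameterization of reduced mutualistic dynamics in the
resilience literature. With B = 0 and β_eff = 0 the equilibria are exactly
{0, C, K}. The Allee effect makes the model bistable at low β_eff: sparse
networks settle in a collapsed state, and recovery exhibits a tipping point
as reintroductions raise β_eff.

### Integration and criteria

All models integrate with LSODA (stiff-safe, rtol 10⁻⁸ / atol 10⁻¹⁰),
sampled at unit time steps and clipped at zero (abundances cannot be
negative). One step represents four months; the horizon is 300 steps
(100 years). Integration proceeds in chunks and stops early once settled.

- **Settling time (ST)**: the first sampled step from which every state
  variable changes by less than 10⁻⁶ over each of the next 5 steps. A
  never-settling run gets the sentinel ST = 300 with `settled = False`
  (reported as censored in summaries).
- **Abundance (X)**: mean final abundance over surviving state variables
  (a `sum` variant is available).
- **Persistence (P)**: surviving weight / reference species count. A state
  variable survives if its final abundance exceeds 10⁻⁴. For the reduced
  models, each compartment carries the number of species it represents as
  weight, so P remains comparable across models.

## Perturbation and cascade

A scenario removes `round_half_away_from_zero(fraction × pool size)`
species (20% of 31 → 6) from the chosen side(s). Kinds: `random` (uniform),
`generalist_preferred` (probability ∝ degree) and `specialist_preferred`
(∝ 1/degree), sampled sequentially without replacement with degrees
recomputed after every draw (a `frozen_weights` flag keeps the original
degrees). Under obligate mutualism, any species with no surviving partner
then goes extinct; pruning repeats to a fixpoint. The resulting secondary
set is order-invariant in the primaries (property-tested, and checked
against a naive fixpoint oracle).

## Restoration

The reintroduction pool is primary ∪ secondary removals. Orders:

- `degree`, `closeness`, `betweenness`: descending centrality computed on
  the original network (ties broken by ascending label);
  `reference_network="current"` re-ranks on the partially restored network
  after every step instead;
- `beta_eff_greedy`: at each step add the candidate that maximizes β_eff of
  the one-mode projection of the partially restored network;
- `random`: seeded shuffle (the null).

Each step reinstates one species with all its original links to
currently-present species, at initial abundance 10⁻⁶. By default abundances
carry forward between steps (the community keeps its state while species
are added); `carry_forward=False` re-initializes every step instead. Small
pools (≤ 8 species by default) can be exhaustively enumerated
(`enumerate_pathways`) to bound strategy curves by the min/max envelope of
all k! orders.

## Experiment layer

`run_experiment` crosses networks × models × scenarios × fractions ×
strategies × ensembles into a tidy per-step table. All randomness derives
from a single master seed through a CRC32 per-cell hash, so any cell is
independently reproducible; the perturbation of a (network, scenario,
fraction, ensemble) cell is shared across models and strategies so that
strategies are compared on the same degraded state.

Summaries average criteria over steps within a run, then over ensembles.
The winner of a cell maximizes X or P, or minimizes ST; exact ties fall back
to X, then ST, then label order, and the margin is the best-vs-rest
difference as a percentage of the best value. The two-sample KS test is an
explicit ECDF sweep with the asymptotic Kolmogorov p-value (Stephens
small-sample correction), verified against a brute-force oracle and an
independent implementation. Attribute–criterion analyses min-max normalize
both sides and report Spearman rank correlations, per-attribute linear
slopes and a joint OLS R².

## Problem sizes and runtime

The acceptance suite uses 50-species networks for strategy-quality
properties (10 networks × 5 strategies × 10 ensembles, 1-D model, ≈ 30 s)
and the 27-network suite for correlation signs (1-D and 2-D, ≈ 45 s). The
n-D model is reserved for small fixtures (it costs seconds per run at
S ≈ 50).

## Limitations

- **The 1-D model cannot differentiate persistence across strategies**: all
  present species share one effective abundance, so P depends only on
  whether that abundance clears the extinction threshold. Consequently the
  expectation that the random null settles fastest (because it leaves fewer
  persisting species to stabilize) does not hold at 1-D resolution; under
  the 1-D model the random null is typically *slowest*, since its gradual
  β_eff growth holds the system near the tipping point where relaxation is
  slow (critical slowing down). The corresponding acceptance test is kept
  as specified and fails by design; the property requires per-species
  dynamics with dynamically obligate mutualism (negative intrinsic growth).
- The generator spans (S, A, C, heterogeneity) only; empirical webs have
  additional structure (modularity, forbidden links, weights) that is out
  of scope.
- Settling is detected on unit-step samples; oscillations faster than the
  sampling step would be aliased (none arise at the default parameters,
  where dynamics are monotone or damped).
- The 2-D effective-β fold-in assumes mean-field interspecific competition;
  it is exact only for homogeneous guilds and degrades gracefully with
  heterogeneity.
- The KS p-value is asymptotic; for very small samples it is approximate
  (the statistic itself is exact).
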