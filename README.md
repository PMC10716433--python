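# ecorestore

Collapse and restoration of mutualistic plant–pollinator networks.

`ecorestore` simulates species-loss perturbations and the secondary-extinction
cascades they trigger on bipartite mutualistic networks, then compares
network-topology-guided species-reintroduction strategies against a random
null. Recovery is scored with community dynamics at three levels of
resolution, using three criteria: mean abundance (X), settling time (ST) and
persistence (P).

## Scientific background

Plant–pollinator communities form bipartite networks whose architecture —
size S, asymmetry A (pollinator-to-plant ratio), connectance C and
nestedness (NODF) — shapes their robustness. When species are lost (at
random, generalists first, or specialists first), obligate mutualism
propagates the damage: any species left with no surviving partner goes
secondarily extinct, and the pruning repeats to a fixpoint.

Restoration reverses the collapse one species per step. The order matters.
This package ranks reintroduction candidates by degree, harmonic closeness or
betweenness centrality, by greedy maximization of the topological resilience
parameter β_eff (the weighted nearest-neighbor degree of the one-mode
projection), or uniformly at random, and integrates community dynamics to
steady state between steps.

Three dynamical models score each recovery path:

- **n-D (per-species)**: each plant P_i and pollinator A_j follows logistic
  growth with interspecific competition and a saturating (Holling type II)
  mutualistic benefit, γ_ij = ε_ij·γ0/D_i^p, plus a small immigration term.
- **2-D (per-guild)**: one effective abundance per guild, coupled through
  degree-weighted average mutualistic strengths ⟨γ⟩.
- **1-D (whole community)**: a single effective abundance with an Allee
  effect; the network enters only through β_eff, so sparse networks can sit
  in a collapsed low-abundance state and dense nested ones escape it.

On top sits a seeded factorial experiment layer (networks × models ×
scenarios × removal fractions × strategies × ensembles) with winner
identification, a two-sample Kolmogorov–Smirnov test and attribute–criterion
correlations.

## Worked example

Collapse a nested 50-species synthetic network with a generalist-preferred
60% removal, then compare every restoration strategy under the 1-D model
(`examples/05_restoration_strategies.py`):

```python
import ecorestore as er

net = er.generate(er.GeneratorConfig(20, 30, 0.2, 2.0, seed=5))
out = er.perturb(net, er.PerturbationScenario(
    "generalist_preferred", 0.6, "both", seed=1))

for kind in er.STRATEGY_KINDS:
    strat = er.RestorationStrategy(kind=kind, seed=9)
    seq = er.restoration_sequence(net, out, strat)
    run = er.simulate_restoration(net, out, seq, "1d", strategy=strat)
    print(kind, run.mean_criteria())
```

Output (removal of 30 primaries cascades to 20 secondary extinctions, so all
50 species are reintroduced):

```
strategy           mean X  mean ST  final P
degree             15.156      2.3     1.00
closeness          15.178      2.5     1.00
betweenness        14.486      3.2     1.00
beta_eff_greedy     6.251      1.0     1.00
random              8.789      1.9     1.00
```

Centrality-guided reintroduction (degree, closeness, betweenness — which
agree within a few percent) holds mean abundance far above the random null
along the recovery path, because putting hubs back first rebuilds β_eff
quickly and lifts the community past the Allee tipping point early.

The other narrative scripts in `examples/` cover network metrics
(`01`), the synthetic generator (`02`), perturbation cascades (`03`), the
three dynamical models (`04`) and the full experiment/statistics layer
(`06`). Each runs in seconds with plain `python examples/<script>.py`.

## Command line

A thin CLI wraps the library for shell workflows:

```bash
ecorestore generate --seed 1 --out networks/          # 27-network suite
ecorestore run --config sweep.yaml --seed 1 --out results/
ecorestore enumerate --network networks/synthetic_000.csv --fraction 0.2 --out env.csv
ecorestore report --results results/results.csv --out report/
```

## Layout

- `src/ecorestore/network.py` — bipartite networks, NODF, centralities,
  projections, β_eff, incidence I/O
- `src/ecorestore/generate.py` — synthetic network generator and suite
- `src/ecorestore/dynamics.py` — the three models, integration, criteria
- `src/ecorestore/perturb.py` — removal scenarios and extinction cascades
- `src/ecorestore/restore.py` — strategies, recovery simulation, pathway
  enumeration
- `src/ecorestore/experiment.py` — factorial sweeps, winners, statistics
- `src/ecorestore/cli.py` — command-line front end
- `docs/methods.md` — models, parameters, numerical conventions, limitations
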