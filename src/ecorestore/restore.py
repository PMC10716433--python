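"""Species-reintroduction strategies and sequential recovery simulation.

After a perturbation has degraded a network, extirpated species are put
back one at a time; each reintroduction restores the species together with
its original mutualistic links to the species currently present, and the
community is re-equilibrated under the chosen dynamical model.  The order
of reintroduction is the strategy under study:

* ``degree``, ``closeness``, ``betweenness`` — descending centrality in the
  original intact network (or, optionally, re-ranked on the partially
  restored network at every step);
* ``beta_eff_greedy`` — at each step reinsert the species giving the
  largest increase in the nearest-neighbour weighted degree of the
  projected network;
* ``random`` — a seeded random order, the null model.

For small removal sets every one of the k! orderings can be enumerated to
map the full solution space that the guided strategies are judged against.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np

from . import dynamics
from .dynamics import (CriteriaRecord, NDParams, OneDParams, Trajectory,
                       TwoDParams, criteria, integrate)
from .network import (BipartiteNetwork, NetworkAttributes, Side, attributes,
                      beta_eff, centrality, project)
from .perturb import PerturbationOutcome

__all__ = [
    "RestorationStrategy",
    "RestorationRun",
    "rank_sequence",
    "beta_eff_greedy_sequence",
    "restoration_sequence",
    "simulate_restoration",
    "enumerate_pathways",
    "STRATEGY_KINDS",
]

STRATEGY_KINDS = ("degree", "closeness", "betweenness", "beta_eff_greedy", "random")
StrategyKind = Literal["degree", "closeness", "betweenness", "beta_eff_greedy", "random"]


@dataclass(frozen=True)
class RestorationStrategy:
    kind: StrategyKind
    reference_network: Literal["original", "current"] = "original"
    seed: int = 0
    side: Side = "plants"  # projection side for beta_eff_greedy

    def __post_init__(self) -> None:
        if self.kind not in STRATEGY_KINDS:
            raise ValueError(f"unknown strategy kind {self.kind!r}")


@dataclass(frozen=True)
class RestorationRun:
    """One full recovery simulation: the reintroduction order, the (X, ST, P)
    record after every step, and the network attributes along the way."""

    strategy: RestorationStrategy
    sequence: tuple[str, ...]
    per_step: tuple[CriteriaRecord, ...]
    step_attributes: tuple[NetworkAttributes, ...] = field(repr=False, default=())
    baseline: CriteriaRecord | None = None
    failed: bool = False

    def mean_criteria(self, max_steps: int = dynamics.MAX_STEPS) -> dict[str, float]:
        """Step-averaged criteria of this run (sentinel ST enters as the
        horizon; the censored count is reported alongside)."""
        if not self.per_step:
            return {"X": 0.0, "ST": float(max_steps), "P": 0.0, "censored": 0}
        X = float(np.mean([r.abundance_X for r in self.per_step]))
        ST = float(np.mean([r.settling_time_ST for r in self.per_step]))
        P = float(np.mean([r.persistence_P for r in self.per_step]))
        censored = sum(not r.settled for r in self.per_step)
        return {"X": X, "ST": ST, "P": P, "censored": censored}


# ---------------------------------------------------------------------------
# sequencing
# ---------------------------------------------------------------------------


def _ordered(scores: dict[str, float], subset: Iterable[str]) -> list[str]:
    """Descending score over ``subset``; ties broken by ascending label."""
    subset = list(subset)
    return sorted(subset, key=lambda s: (-scores[s], s))


def rank_sequence(original_net: BipartiteNetwork, removed: Iterable[str],
                  strategy: RestorationStrategy) -> list[str]:
    """Static reintroduction order from centrality on the intact network.

    ``random`` returns a seeded shuffle of the removal pool (labels sorted
    first so the permutation is a pure function of the seed).
    """
    removed = sorted(set(removed))
    missing = [s for s in removed if s not in original_net.species]
    if missing:
        raise KeyError(f"species not in original network: {missing}")
    if not removed:
        return []
    if strategy.kind == "random":
        rng = np.random.default_rng(np.random.SeedSequence(strategy.seed))
        out = list(removed)
        rng.shuffle(out)
        return out
    if strategy.kind == "beta_eff_greedy":
        raise ValueError("beta_eff_greedy ordering depends on the degraded "
                         "network; use beta_eff_greedy_sequence")
    scores = centrality(original_net, strategy.kind).scores
    return _ordered(dict(scores), removed)


def _restored_subnet(original: BipartiteNetwork, present: Iterable[str]) -> BipartiteNetwork:
    """Original-network restriction to ``present``; reintroduced species may
    be temporarily isolated, which is legal mid-restoration."""
    return original.subnetwork(present, allow_isolated=True)


def beta_eff_greedy_sequence(original_net: BipartiteNetwork,
                             outcome_or_present: PerturbationOutcome | Iterable[str],
                             removed: Iterable[str], *, side: Side = "plants",
                             weighted: bool = True) -> list[str]:
    """Greedy order maximising the incremental beta_eff gain at every step.

    Each remaining candidate is tentatively reinserted (with its original
    links to the species currently present), the nearest-neighbour weighted
    degree of the chosen-side projection is evaluated, and the maximiser is
    committed.  Ties break on ascending label.
    """
    if isinstance(outcome_or_present, PerturbationOutcome):
        present = set(outcome_or_present.degraded_net.species)
    else:
        present = set(outcome_or_present)
    remaining = sorted(set(removed))
    order: list[str] = []
    while remaining:
        best, best_val = None, -np.inf
        for cand in remaining:
            trial = _restored_subnet(original_net, present | {cand})
            val = beta_eff(project(trial, side), weighted=weighted)
            if val > best_val + 1e-12:
                best, best_val = cand, val
        order.append(best)
        present.add(best)
        remaining.remove(best)
    return order


def _dynamic_rank_next(original_net: BipartiteNetwork, present: set[str],
                       remaining: list[str], kind: StrategyKind) -> str:
    """Most central remaining candidate when it is scored on the partially
    restored network (candidate included with its original links)."""
    best, best_score = None, -np.inf
    for cand in sorted(remaining):
        trial = _restored_subnet(original_net, present | {cand})
        score = centrality(trial, kind).scores[cand]
        if score > best_score + 1e-12:
            best, best_score = cand, score
    return best


def restoration_sequence(original_net: BipartiteNetwork,
                         outcome: PerturbationOutcome,
                         strategy: RestorationStrategy) -> list[str]:
    """Full reintroduction order for a strategy over primary + secondary
    extinctions (recovery targets complete network recovery)."""
    removed = sorted(outcome.all_removed)
    if strategy.kind == "beta_eff_greedy":
        return beta_eff_greedy_sequence(original_net, outcome, removed,
                                        side=strategy.side)
    if strategy.kind != "random" and strategy.reference_network == "current":
        present = set(outcome.degraded_net.species)
        remaining = list(removed)
        order: list[str] = []
        while remaining:
            nxt = _dynamic_rank_next(original_net, present, remaining, strategy.kind)
            order.append(nxt)
            present.add(nxt)
            remaining.remove(nxt)
        return order
    return rank_sequence(original_net, removed, strategy)


def enumerate_pathways(removed: Iterable[str], cap: int = 8) -> Iterator[tuple[str, ...]]:
    """All reintroduction orders, lexicographic in species label.

    k removed species yield k! pathways; a cap guards against combinatorial
    blow-up (use random sampling of orders beyond it).
    """
    removed = sorted(set(removed))
    if len(removed) > cap:
        raise ValueError(
            f"{len(removed)} species give {len(removed)}! pathways; above the cap "
            f"of {cap} — sample random sequences instead of enumerating"
        )
    return itertools.permutations(removed)


# ---------------------------------------------------------------------------
# recovery simulation
# ---------------------------------------------------------------------------


def _model_weights(model: str, net: BipartiteNetwork) -> np.ndarray:
    """Species count represented by each state entry (persistence weights)."""
    if model == "nd":
        return np.ones(net.n_plants + net.m_pollinators)
    if model == "2d":
        return np.array([net.n_plants, net.m_pollinators], dtype=float)
    return np.array([net.n_plants + net.m_pollinators], dtype=float)


def _default_params(model: str, net: BipartiteNetwork, overrides: dict):
    if model == "nd":
        return NDParams.for_network(net, **overrides)
    if model == "2d":
        return TwoDParams.from_network(net, **overrides)
    if model == "1d":
        return OneDParams.from_network(net, **overrides)
    raise ValueError(f"unknown model {model!r}")


def _equilibrate(model: str, original: BipartiteNetwork, present: set[str],
                 carried: dict[str, float] | np.ndarray | None,
                 param_overrides: dict, side: Side,
                 max_steps: int) -> tuple[CriteriaRecord, dict[str, float] | np.ndarray]:
    """Integrate the current community to steady state and score it."""
    n_reference = len(original.species)
    current = _restored_subnet(original, present)
    if not present:
        rec = CriteriaRecord(0.0, 0, True, 0.0)
        return rec, {} if model == "nd" else np.array([])
    if model == "nd":
        params = NDParams.for_network(original, **param_overrides)
        p_idx = [i for i, s in enumerate(original.plant_labels) if s in present]
        a_idx = [j for j, s in enumerate(original.pollinator_labels) if s in present]
        params = params.restrict(original, p_idx, a_idx)
        labels = current.species
        prev = carried or {}
        init = np.array([prev.get(s, dynamics.INITIAL_ABUNDANCE) for s in labels])
        traj = integrate("nd", params, current, init, max_steps=max_steps)
        rec = criteria(traj, n_reference=n_reference,
                       weights=_model_weights("nd", current), max_steps=max_steps)
        return rec, dict(zip(labels, traj.final_state))
    if model == "2d":
        params = TwoDParams.from_network(current, **param_overrides)
        init = (carried if isinstance(carried, np.ndarray) and carried.size == 2
                else np.full(2, dynamics.INITIAL_ABUNDANCE))
        traj = integrate("2d", params, None, init, max_steps=max_steps)
        rec = criteria(traj, n_reference=n_reference,
                       weights=_model_weights("2d", current), max_steps=max_steps)
        return rec, traj.final_state
    # 1d
    params = OneDParams.from_network(current, side=side, **param_overrides)
    init = (carried if isinstance(carried, np.ndarray) and carried.size == 1
            else np.array([dynamics.INITIAL_ABUNDANCE]))
    traj = integrate("1d", params, None, init, max_steps=max_steps)
    rec = criteria(traj, n_reference=n_reference,
                   weights=_model_weights("1d", current), max_steps=max_steps)
    return rec, traj.final_state


def simulate_restoration(original_net: BipartiteNetwork,
                         outcome: PerturbationOutcome,
                         sequence: Sequence[str],
                         model: Literal["nd", "2d", "1d"],
                         *, strategy: RestorationStrategy | None = None,
                         param_overrides: dict | None = None,
                         side: Side = "plants",
                         carry_forward: bool = True,
                         max_steps: int = dynamics.MAX_STEPS,
                         record_attributes: bool = True) -> RestorationRun:
    """Reintroduce species in ``sequence`` one at a time and re-equilibrate.

    Every reintroduction adds the species with its original links to the
    currently present community and gives it the standard initial abundance
    (1e-6); surviving species carry their abundances forward between steps
    unless ``carry_forward=False``, in which case every step restarts all
    species from 1e-6.  The (X, ST, P) criteria are recorded after each
    step, with persistence always measured against the intact network's
    species count.
    """
    removed_pool = set(outcome.all_removed)
    if set(sequence) != removed_pool or len(sequence) != len(removed_pool):
        raise ValueError("sequence must be a permutation of the removed species")
    overrides = dict(param_overrides or {})
    present = set(outcome.degraded_net.species)
    per_step: list[CriteriaRecord] = []
    step_attrs: list[NetworkAttributes] = []
    failed = False

    try:
        baseline, carried = _equilibrate(model, original_net, present, None,
                                         overrides, side, max_steps)
    except dynamics.IntegrationError:
        baseline, carried, failed = None, None, True

    for sp in sequence:
        if failed:
            break
        present.add(sp)
        if model == "nd" and isinstance(carried, dict):
            carried[sp] = dynamics.INITIAL_ABUNDANCE
        if not carry_forward:
            carried = None
        try:
            rec, carried = _equilibrate(model, original_net, present, carried,
                                        overrides, side, max_steps)
        except dynamics.IntegrationError:
            failed = True
            break
        per_step.append(rec)
        if record_attributes:
            cur = _restored_subnet(original_net, present)
            step_attrs.append(attributes(cur))

    return RestorationRun(
        strategy=strategy or RestorationStrategy("random"),
        sequence=tuple(sequence),
        per_step=tuple(per_step),
        step_attributes=tuple(step_attrs),
        baseline=baseline,
        failed=failed,
    )
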