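"""Species-removal perturbations and obligate-mutualism extinction cascades.

A perturbation removes a fixed fraction of species (primary extinctions)
drawn under one of three scenarios — uniformly at random, generalist-
preferred (probability proportional to degree) or specialist-preferred
(probability inversely proportional to degree).  Because mutualism is
obligate, any species left without partners goes secondarily extinct; the
cascade iterates until no isolated species remain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .network import BipartiteNetwork

__all__ = ["PerturbationScenario", "PerturbationOutcome", "sample_primary",
           "cascade", "perturb", "round_half_up"]

ScenarioKind = Literal["random", "generalist_preferred", "specialist_preferred"]
TargetSide = Literal["plants", "pollinators", "both"]


def round_half_up(x: float) -> int:
    """Round half away from zero (20% of a 31-species pool -> 6 species)."""
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class PerturbationScenario:
    kind: ScenarioKind
    fraction_removed: float
    target_side: TargetSide = "both"
    seed: int = 0
    frozen_weights: bool = False  # weight by intact-network degrees instead of current

    def __post_init__(self) -> None:
        if not (0 < self.fraction_removed < 1):
            raise ValueError("fraction_removed must lie in (0, 1)")
        if self.kind not in ("random", "generalist_preferred", "specialist_preferred"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")


@dataclass(frozen=True)
class PerturbationOutcome:
    primary_removed: tuple[str, ...]
    secondary_removed: tuple[str, ...]
    degraded_net: BipartiteNetwork

    @property
    def all_removed(self) -> tuple[str, ...]:
        return self.primary_removed + self.secondary_removed

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "primary_removed": list(self.primary_removed),
            "secondary_removed": list(self.secondary_removed),
        }, indent=2))


def _pool(net: BipartiteNetwork, side: TargetSide) -> list[str]:
    if side == "plants":
        return list(net.plant_labels)
    if side == "pollinators":
        return list(net.pollinator_labels)
    return list(net.species)


def sample_primary(net: BipartiteNetwork, scenario: PerturbationScenario) -> list[str]:
    """Draw the ordered primary-removal list for a scenario.

    Species are drawn sequentially without replacement with probability
    proportional to degree (generalist-preferred), inverse degree
    (specialist-preferred) or uniformly.  By default degrees are recomputed
    on the network with already-drawn species deleted; ``frozen_weights``
    keeps the intact-network degrees throughout.  A species isolated
    mid-sequence counts as degree zero: it can no longer be drawn under the
    generalist rule and is drawn first under the specialist rule.
    """
    pool = _pool(net, scenario.target_side)
    k = round_half_up(scenario.fraction_removed * len(pool))
    if k == 0:
        raise ValueError(
            f"fraction {scenario.fraction_removed} of {len(pool)} species rounds to zero"
        )
    rng = np.random.default_rng(np.random.SeedSequence(scenario.seed))
    frozen_deg = net.degrees()
    chosen: list[str] = []
    remaining = list(pool)
    for _ in range(k):
        if scenario.frozen_weights:
            deg = frozen_deg
        else:
            deg = net.subnetwork(
                set(net.species) - set(chosen), allow_isolated=True
            ).degrees()
        d = np.array([deg[s] for s in remaining], dtype=float)
        if scenario.kind == "random":
            w = np.ones_like(d)
        elif scenario.kind == "generalist_preferred":
            w = d.copy()
            if w.sum() == 0:
                w = np.ones_like(d)
        else:  # specialist_preferred
            if np.any(d == 0):
                w = (d == 0).astype(float)
            else:
                w = 1.0 / d
        pick = rng.choice(len(remaining), p=w / w.sum())
        chosen.append(remaining.pop(pick))
    return chosen


def cascade(net: BipartiteNetwork, removed: Sequence[str]) -> PerturbationOutcome:
    """Apply removals and iterate secondary extinctions to a fixed point.

    Any species whose degree drops to zero loses its obligate partners and
    is deleted; the process repeats until no isolated species remain.  The
    surviving set is independent of the order of the removal list.
    """
    removed_set = set(removed)
    unknown = removed_set - set(net.species)
    if unknown:
        raise KeyError(f"species not in network: {sorted(unknown)}")
    present = [s for s in net.species if s not in removed_set]
    current = net.subnetwork(present, allow_isolated=True)
    secondary: list[str] = []
    while True:
        deg = current.degrees()
        dead = sorted(s for s, d in deg.items() if d == 0)
        # a fully emptied side kills the other side too (no possible partners)
        if not dead and (current.n_plants == 0) != (current.m_pollinators == 0):
            dead = sorted(current.species)
        if not dead:
            break
        secondary.extend(dead)
        current = current.subnetwork(set(current.species) - set(dead),
                                     allow_isolated=True)
    degraded = BipartiteNetwork(current.plant_labels, current.pollinator_labels,
                                current.incidence)
    return PerturbationOutcome(tuple(removed), tuple(secondary), degraded)


def perturb(net: BipartiteNetwork, scenario: PerturbationScenario) -> PerturbationOutcome:
    """Sample primary removals under a scenario and run the cascade."""
    return cascade(net, sample_primary(net, scenario))
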