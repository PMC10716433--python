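"""Ensemble sweeps, winner identification, and the statistics layer.

The full factorial experiment crosses networks x dynamical models x
perturbation scenarios x removal fractions x restoration strategies, with a
fixed number of stochastic ensembles per combination (default 10).  All
randomness derives from one master seed through a stable per-cell hash, so
any cell — and the whole sweep — is exactly reproducible and resumable.
Results are kept as a tidy table with one row per restoration step.

On top of the table sit the analyses used to compare strategies: step- and
ensemble-averaged criteria, per-cell "winning" strategies with best-vs-rest
margins, a two-sample Kolmogorov-Smirnov test (ECDF sweep implemented
in-repo), and Spearman / OLS relationships between restoration criteria and
network attributes.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import dynamics
from .network import BipartiteNetwork
from .perturb import PerturbationScenario, cascade, sample_primary
from .restore import (RestorationStrategy, restoration_sequence,
                      simulate_restoration)

__all__ = [
    "ExperimentResult",
    "cell_seed",
    "run_experiment",
    "summarize",
    "identify_winner",
    "winner_table",
    "ks_two_sample",
    "attribute_correlations",
]

ATTRIBUTE_COLS = ("S", "A", "C", "NODF")
CRITERIA_COLS = ("X", "ST", "P")
# higher is better for abundance and persistence, lower for settling time
_SENSE = {"X": 1, "P": 1, "ST": -1}


def cell_seed(master_seed: int, *parts) -> int:
    """Stable, platform-independent seed below 2**31 for one experiment cell."""
    key = "|".join(str(p) for p in (master_seed, *parts))
    return zlib.crc32(key.encode()) & 0x7FFFFFFF


@dataclass
class ExperimentResult:
    """Tidy per-step results plus the provenance needed to reproduce them."""

    table: pd.DataFrame
    master_seed: int
    config: dict = field(default_factory=dict)

    def save(self, path) -> None:
        self.table.to_csv(path, index=False)


def run_experiment(networks: Mapping[str, BipartiteNetwork],
                   models: Sequence[str] = ("1d", "2d", "nd"),
                   scenario_kinds: Sequence[str] = ("random",
                                                    "generalist_preferred",
                                                    "specialist_preferred"),
                   fractions: Sequence[float] = (0.3, 0.6, 0.9),
                   strategy_kinds: Sequence[str] = ("degree", "closeness",
                                                    "betweenness",
                                                    "beta_eff_greedy", "random"),
                   *, ensembles: int = 10, master_seed: int = 0,
                   target_side: str = "both",
                   param_overrides: dict | None = None,
                   max_steps: int = dynamics.MAX_STEPS,
                   record_attributes: bool = True,
                   progress: bool = False) -> ExperimentResult:
    """Full factorial sweep; one row per restoration step.

    The perturbation of a given (network, scenario, fraction, ensemble) is
    shared across models and strategies, so strategies are compared on the
    same degraded state.  Failing cells are flagged in the ``failed`` column
    and the sweep continues.
    """
    rows: list[dict] = []
    combos = [(nid, sk, fr, e) for nid in networks for sk in scenario_kinds
              for fr in fractions for e in range(1, ensembles + 1)]
    iterator = combos
    if progress:
        from tqdm import tqdm
        iterator = tqdm(combos, desc="experiment cells")
    for nid, sk, fr, ens in iterator:
        net = networks[nid]
        pseed = cell_seed(master_seed, "perturb", nid, sk, fr, ens)
        scen = PerturbationScenario(kind=sk, fraction_removed=fr,
                                    target_side=target_side, seed=pseed)
        outcome = cascade(net, sample_primary(net, scen))
        for model in models:
            for strat_kind in strategy_kinds:
                sseed = cell_seed(master_seed, "strategy", nid, sk, fr,
                                  strat_kind, ens)
                strat = RestorationStrategy(kind=strat_kind, seed=sseed)
                seq = restoration_sequence(net, outcome, strat)
                run = simulate_restoration(
                    net, outcome, seq, model, strategy=strat,
                    param_overrides=param_overrides, max_steps=max_steps,
                    record_attributes=record_attributes)
                for step, rec in enumerate(run.per_step, start=1):
                    row = {
                        "network_id": nid, "model": model, "scenario": sk,
                        "fraction": fr, "strategy": strat_kind,
                        "ensemble": ens, "step": step,
                        "species": run.sequence[step - 1],
                        "X": rec.abundance_X, "ST": rec.settling_time_ST,
                        "P": rec.persistence_P, "settled": rec.settled,
                        "failed": run.failed,
                    }
                    if record_attributes and run.step_attributes:
                        att = run.step_attributes[step - 1]
                        row.update({"S": att.size_S, "A": att.asymmetry_A,
                                    "C": att.connectance_C,
                                    "NODF": att.nestedness_NODF})
                    rows.append(row)
    table = pd.DataFrame(rows)
    cfg = {"models": list(models), "scenarios": list(scenario_kinds),
           "fractions": list(fractions), "strategies": list(strategy_kinds),
           "ensembles": ensembles, "target_side": target_side}
    return ExperimentResult(table=table, master_seed=master_seed, config=cfg)


def summarize(result: ExperimentResult | pd.DataFrame) -> pd.DataFrame:
    """Per-strategy mean criteria: average over restoration steps within each
    ensemble run, then over ensembles.

    Averaging over steps first makes networks of different sizes (hence
    restoration sequences of different lengths) comparable.  Never-settled
    steps enter with the sentinel ST (the simulation horizon); their count is
    reported in ``censored``.
    """
    table = result.table if isinstance(result, ExperimentResult) else result
    if table.empty:
        raise ValueError("cannot summarize an empty result")
    keys = ["network_id", "model", "scenario", "fraction", "strategy"]
    per_run = (table.groupby(keys + ["ensemble"], sort=True)
               .agg(X=("X", "mean"), ST=("ST", "mean"), P=("P", "mean"),
                    censored=("settled", lambda s: int((~s).sum())))
               .reset_index())
    return (per_run.groupby(keys, sort=True)
            .agg(X=("X", "mean"), ST=("ST", "mean"), P=("P", "mean"),
                 censored=("censored", "sum"))
            .reset_index())


def identify_winner(summary: pd.DataFrame, criterion: str) -> tuple[str, float]:
    """Winning strategy for one summarized cell.

    Higher abundance (X) and persistence (P) win; lower settling time (ST)
    wins.  Exact ties fall back to abundance, then settling time, then label
    order.  Returns (strategy, margin) where the margin is the best-vs-rest
    difference as a percentage of the best value.
    """
    if criterion not in _SENSE:
        raise ValueError(f"unknown criterion {criterion!r}")
    if summary["strategy"].nunique() < 2:
        raise ValueError("need at least two strategies to pick a winner")

    def sort_key(row) -> tuple:
        return (-_SENSE[criterion] * row[criterion],
                -row["X"], row["ST"], row["strategy"])

    ranked = sorted(summary.to_dict("records"), key=sort_key)
    best, runner = ranked[0], ranked[1]
    denom = abs(best[criterion])
    margin = (abs(best[criterion] - runner[criterion]) / denom * 100.0
              if denom > 0 else 0.0)
    return best["strategy"], margin


def winner_table(summary: pd.DataFrame,
                 criteria: Sequence[str] = CRITERIA_COLS) -> pd.DataFrame:
    """Winner + margin for every (network, model, scenario, fraction,
    criterion) cell of a summarized experiment."""
    keys = ["network_id", "model", "scenario", "fraction"]
    rows = []
    for cell, grp in summary.groupby(keys, sort=True):
        for crit in criteria:
            win, margin = identify_winner(grp, crit)
            rows.append(dict(zip(keys, cell)) | {
                "criterion": crit, "winner": win, "margin_pct": margin})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def _kolmogorov_sf(lam: float, terms: int = 101) -> float:
    """Asymptotic Kolmogorov distribution survival function."""
    if lam <= 0:
        return 1.0
    k = np.arange(1, terms)
    p = 2.0 * np.sum((-1.0) ** (k - 1) * np.exp(-2.0 * (k * lam) ** 2))
    return float(min(max(p, 0.0), 1.0))


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test via an explicit ECDF sweep.

    D is the supremum of |ECDF_a - ECDF_b| over the pooled sample points;
    the p-value uses the asymptotic Kolmogorov distribution with the
    small-sample Stephens correction.
    """
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least two observations")
    grid = np.union1d(a, b)
    cdf_a = np.searchsorted(a, grid, side="right") / a.size
    cdf_b = np.searchsorted(b, grid, side="right") / b.size
    D = float(np.max(np.abs(cdf_a - cdf_b)))
    en = np.sqrt(a.size * b.size / (a.size + b.size))
    p = _kolmogorov_sf((en + 0.12 + 0.11 / en) * D)
    return D, p


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = np.min(x), np.max(x)
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def attribute_correlations(result: ExperimentResult | pd.DataFrame,
                           model: str, criterion: str = "X",
                           attributes: Sequence[str] = ATTRIBUTE_COLS
                           ) -> dict:
    """Relationships between one restoration criterion and the network
    attributes for one model.

    The criterion and every attribute are min-max normalized to [0, 1]; the
    function reports, per attribute, the Spearman rank correlation and the
    simple-linear-regression slope, plus the R^2 of one multivariate OLS fit
    of the criterion on all attributes jointly.  Zero-variance attributes
    are excluded with a warning.
    """
    table = result.table if isinstance(result, ExperimentResult) else result
    attributes = list(attributes)
    sub = table[table["model"] == model].dropna(subset=[criterion, *attributes])
    if sub[attributes].nunique().max() < 3:
        raise ValueError("need at least 3 distinct attribute values")
    y = _minmax(sub[criterion].to_numpy(dtype=float))
    kept, per_attr = [], []
    for att in attributes:
        x = sub[att].to_numpy(dtype=float)
        if np.min(x) == np.max(x):
            warnings.warn(f"attribute {att} has zero variance; excluded",
                          stacklevel=2)
            continue
        xn = _minmax(x)
        rho, rho_p = stats.spearmanr(xn, y)
        slope = float(np.polyfit(xn, y, 1)[0])
        kept.append(att)
        per_attr.append({"attribute": att, "spearman_rho": float(rho),
                         "spearman_p": float(rho_p), "coef": slope})
    X = np.column_stack([_minmax(sub[a].to_numpy(dtype=float)) for a in kept])
    design = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 0.0
    return {"per_attribute": pd.DataFrame(per_attr), "r_squared": r2,
            "n": int(len(y)), "criterion": criterion, "model": model}
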