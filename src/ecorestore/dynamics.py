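"""Community dynamics for mutualistic networks at three levels of resolution.

Three nested model families describe abundances on a plant-pollinator
network:

* the **n-D model**: one ODE per species, with logistic growth, pairwise
  competition, a saturating (Holling type-II) mutualistic benefit and a
  small immigration term;
* the **2-D model**: the same structure collapsed to one effective plant
  and one effective pollinator abundance, with network topology entering
  through degree-weighted average mutualistic strengths;
* the **1-D model**: a single effective abundance for the whole community
  driven by migration, logistic growth with an Allee threshold and a
  mutualism term scaled by the nearest-neighbour weighted degree
  ``beta_eff`` of the one-mode projected network.

Integration is adaptive and stiff-safe internally but trajectories are
sampled at unit time steps (one step = 4 months; 300 steps = 100 years),
and the settling-time / abundance / persistence criteria are computed from
those samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .network import BipartiteNetwork, Side, beta_eff, project

__all__ = [
    "NDParams",
    "TwoDParams",
    "OneDParams",
    "Trajectory",
    "CriteriaRecord",
    "gamma_matrix",
    "mean_gamma",
    "nd_rhs",
    "twod_rhs",
    "oned_rhs",
    "integrate",
    "detect_steady",
    "criteria",
    "MAX_STEPS",
    "SETTLE_TOL",
    "SETTLE_WINDOW",
    "INITIAL_ABUNDANCE",
    "EXTINCT_THRESHOLD",
]

MAX_STEPS = 300          # 100 years at 4 months per step
SETTLE_TOL = 1e-6        # per-step abundance change defining steady state
SETTLE_WINDOW = 5        # consecutive quiet steps required
INITIAL_ABUNDANCE = 1e-6
EXTINCT_THRESHOLD = 1e-4

ModelTag = Literal["nd", "2d", "1d"]


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NDParams:
    """Parameters of the per-species model.

    ``alpha`` are intrinsic growth rates, ``beta`` competition matrices
    (diagonal: intraspecific, off-diagonal: interspecific), ``gamma0`` the
    mutualistic strength scale, ``trade_off_p`` the exponent trading
    interaction strength against the number of partners, ``h`` the
    half-saturation constant of the mutualistic benefit and ``mu``
    immigration.  Defaults follow standard mutualistic-community modelling
    practice: alpha=0.3, beta_intra=1, beta_inter=0.01, h=0.2, mu=1e-4,
    gamma0=1, p=0.5.
    """

    alpha_P: np.ndarray
    alpha_A: np.ndarray
    beta_P: np.ndarray = field(repr=False)
    beta_A: np.ndarray = field(repr=False)
    gamma0: float = 1.0
    trade_off_p: float = 0.5
    h: float = 0.2
    mu_P: float = 1e-4
    mu_A: float = 1e-4

    def __post_init__(self) -> None:
        for name in ("alpha_P", "alpha_A", "beta_P", "beta_A"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(np.diag(self.beta_P) <= 0) or np.any(np.diag(self.beta_A) <= 0):
            raise ValueError("intraspecific competition (beta diagonal) must be positive")
        if self.h < 0 or self.gamma0 < 0:
            raise ValueError("h and gamma0 must be nonnegative")

    @classmethod
    def for_network(cls, net: BipartiteNetwork, *, alpha: float = 0.3,
                    beta_intra: float = 1.0, beta_inter: float = 0.01,
                    gamma0: float = 1.0, trade_off_p: float = 0.5,
                    h: float = 0.2, mu: float = 1e-4) -> "NDParams":
        n, m = net.n_plants, net.m_pollinators
        bP = np.full((n, n), beta_inter)
        np.fill_diagonal(bP, beta_intra)
        bA = np.full((m, m), beta_inter)
        np.fill_diagonal(bA, beta_intra)
        return cls(
            alpha_P=np.full(n, alpha), alpha_A=np.full(m, alpha),
            beta_P=bP, beta_A=bA, gamma0=gamma0, trade_off_p=trade_off_p,
            h=h, mu_P=mu, mu_A=mu,
        )

    def restrict(self, net: BipartiteNetwork, plant_idx: Sequence[int],
                 poll_idx: Sequence[int]) -> "NDParams":
        """Sub-parameterisation for a subset of species (indices into the
        original ordering)."""
        pi = np.asarray(plant_idx, dtype=int)
        ai = np.asarray(poll_idx, dtype=int)
        return replace(
            self,
            alpha_P=self.alpha_P[pi], alpha_A=self.alpha_A[ai],
            beta_P=self.beta_P[np.ix_(pi, pi)], beta_A=self.beta_A[np.ix_(ai, ai)],
        )


@dataclass(frozen=True)
class TwoDParams:
    """Effective two-compartment parameters; the network enters only through
    the degree-weighted average mutualistic strengths."""

    alpha: float = 0.3
    beta: float = 1.0
    h: float = 0.2
    mu: float = 1e-4
    gamma_P_avg: float = 0.0
    gamma_A_avg: float = 0.0

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")

    @classmethod
    def from_network(cls, net: BipartiteNetwork, *, alpha: float = 0.3,
                     beta: float | None = None, beta_intra: float = 1.0,
                     beta_inter: float = 0.01, h: float = 0.2, mu: float = 1e-4,
                     gamma0: float = 1.0, trade_off_p: float = 0.5) -> "TwoDParams":
        """Effective parameters for the current network.

        Unless ``beta`` is given explicitly, the effective self-limitation
        folds the mean interspecific competition a species feels from its
        side into the intraspecific term:
        ``beta = beta_intra + beta_inter * (mean side size - 1)``.
        """
        gP = mean_gamma(net, gamma0, trade_off_p, side="plants")
        gA = mean_gamma(net, gamma0, trade_off_p, side="pollinators")
        if beta is None:
            side_mean = (net.n_plants + net.m_pollinators) / 2
            beta = beta_intra + beta_inter * max(side_mean - 1, 0)
        return cls(alpha=alpha, beta=beta, h=h, mu=mu, gamma_P_avg=gP, gamma_A_avg=gA)


@dataclass(frozen=True)
class OneDParams:
    """Single-effective-abundance parameters.

    ``B`` constant migration, ``K`` carrying capacity, ``C_allee`` the Allee
    threshold below which growth is negative, and ``D``, ``E``, ``H`` the
    saturation constants of the mutualism term whose strength is
    ``beta_eff``.  Defaults (B=0.1, K=5, C_allee=1, D=5, E=0.9, H=0.1) are
    the standard values for mutualistic systems in the resilience-reduction
    literature.
    """

    B: float = 0.1
    K: float = 5.0
    C_allee: float = 1.0
    D: float = 5.0
    E: float = 0.9
    H: float = 0.1
    beta_eff: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.C_allee < self.K):
            raise ValueError("Allee threshold must satisfy 0 < C_allee < K")
        if self.D <= 0:
            raise ValueError("D must be positive so the mutualism term is defined at x=0")

    @classmethod
    def from_network(cls, net: BipartiteNetwork, *, side: Side = "plants",
                     weighted: bool = True, **kwargs: float) -> "OneDParams":
        b = beta_eff(project(net, side), weighted=weighted) if not net.is_empty() else 0.0
        return cls(beta_eff=b, **kwargs)


# ---------------------------------------------------------------------------
# mutualistic strengths
# ---------------------------------------------------------------------------


def _gamma_safe(net: BipartiteNetwork, gamma0: float, p: float,
                side: Side) -> np.ndarray:
    """Like :func:`gamma_matrix` but a partner-less species simply gets a
    zero row (no mutualistic benefit) instead of an error — needed while a
    freshly reintroduced species has no present partners."""
    inc = net.incidence.astype(float)
    eps = inc if side == "plants" else inc.T
    deg = eps.sum(axis=1)
    scale = np.divide(gamma0, deg ** p, out=np.zeros_like(deg), where=deg > 0)
    return eps * scale[:, None]


def gamma_matrix(net: BipartiteNetwork, gamma0: float, p: float,
                 side: Side = "plants") -> np.ndarray:
    """Per-link mutualistic strengths gamma_ij = eps_ij * gamma0 / D_i**p.

    ``D_i`` is the current degree of the *focal* species ``i``: for
    ``side="plants"`` the result is (n_plants, m_pollinators) with rows
    indexed by the benefiting plant; for ``side="pollinators"`` it is the
    transpose layout with rows indexed by the benefiting pollinator.
    """
    if p < 0:
        raise ValueError("trade-off exponent p must be nonnegative")
    inc = net.incidence.astype(float)
    eps = inc if side == "plants" else inc.T
    deg = eps.sum(axis=1)
    if np.any(deg == 0):
        raise ValueError("network contains a species with no partners")
    return _gamma_safe(net, gamma0, p, side)


def mean_gamma(net: BipartiteNetwork, gamma0: float, p: float,
               side: Side = "plants") -> float:
    """Degree-weighted network average of the per-species aggregate
    mutualistic strength, used as <gamma> in the 2-D model.

    Each species' row sum of the per-link strengths is averaged with its
    degree as weight, the same nearest-neighbour weighting that defines
    ``beta_eff``.  Partner-less species carry zero weight.
    """
    if net.is_empty():
        return 0.0
    g = _gamma_safe(net, gamma0, p, side)
    per_species = g.sum(axis=1)
    deg = (g > 0).sum(axis=1).astype(float)
    if deg.sum() == 0:
        return 0.0
    return float(np.dot(deg, per_species) / deg.sum())


# ---------------------------------------------------------------------------
# right-hand sides
# ---------------------------------------------------------------------------


def nd_rhs(state: np.ndarray, params: NDParams, net: BipartiteNetwork) -> np.ndarray:
    """Time derivative of the per-species model.

    ``state`` stacks plant abundances then pollinator abundances in the
    network's label order.
    """
    n, m = net.n_plants, net.m_pollinators
    state = np.asarray(state, dtype=float)
    if state.shape != (n + m,):
        raise ValueError(f"state length {state.shape} does not match network ({n + m})")
    P, A = state[:n], state[n:]
    gP = _gamma_safe(net, params.gamma0, params.trade_off_p, "plants")
    gA = _gamma_safe(net, params.gamma0, params.trade_off_p, "pollinators")
    mutual_P = gP @ A
    mutual_A = gA @ P
    dP = P * (params.alpha_P - params.beta_P @ P + mutual_P / (1 + params.h * mutual_P)) + params.mu_P
    dA = A * (params.alpha_A - params.beta_A @ A + mutual_A / (1 + params.h * mutual_A)) + params.mu_A
    return np.concatenate([dP, dA])


def twod_rhs(state: np.ndarray, params: TwoDParams) -> np.ndarray:
    """Time derivative of the effective (P_eff, A_eff) model."""
    P, A = float(state[0]), float(state[1])
    gPA = params.gamma_P_avg * A
    gAP = params.gamma_A_avg * P
    dP = params.alpha * P - params.beta * P ** 2 + gPA / (1 + params.h * gPA) * P + params.mu
    dA = params.alpha * A - params.beta * A ** 2 + gAP / (1 + params.h * gAP) * A + params.mu
    return np.array([dP, dA])


def oned_rhs(x: float, params: OneDParams) -> float:
    """Time derivative of the single effective abundance.

    With B=0 and beta_eff=0 the right-hand side factorises as
    ``x (1 - x/K)(x/C - 1)``, with roots exactly {0, C_allee, K} and negative
    growth below the Allee threshold.
    """
    x = float(x)
    logistic_allee = x * (1 - x / params.K) * (x / params.C_allee - 1)
    mutual = params.beta_eff * x ** 2 / (params.D + (params.E + params.H) * x)
    return params.B + logistic_allee + mutual


# ---------------------------------------------------------------------------
# integration and criteria
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Trajectory:
    """Abundances sampled at unit time steps (1 step = 4 months)."""

    times: np.ndarray
    states: np.ndarray  # shape (n_times, n_state)
    model_tag: ModelTag

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        states = np.atleast_2d(np.asarray(self.states, dtype=float))
        object.__setattr__(self, "states", states)
        if len(self.times) != states.shape[0]:
            raise ValueError("times and states lengths differ")

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]


@dataclass(frozen=True)
class CriteriaRecord:
    """The (X, ST, P) triple measured after one equilibration."""

    abundance_X: float
    settling_time_ST: int
    settled: bool
    persistence_P: float


class IntegrationError(RuntimeError):
    def __init__(self, message: str, partial: Trajectory | None = None):
        super().__init__(message)
        self.partial = partial


def _rhs_for(model: ModelTag, params, net: BipartiteNetwork | None):
    if model == "nd":
        # precompute the per-link strengths once per integration
        n = net.n_plants
        gP = _gamma_safe(net, params.gamma0, params.trade_off_p, "plants")
        gA = _gamma_safe(net, params.gamma0, params.trade_off_p, "pollinators")

        def rhs(t, y):
            y = np.maximum(y, 0.0)
            P, A = y[:n], y[n:]
            mP = gP @ A
            mA = gA @ P
            dP = P * (params.alpha_P - params.beta_P @ P
                      + mP / (1 + params.h * mP)) + params.mu_P
            dA = A * (params.alpha_A - params.beta_A @ A
                      + mA / (1 + params.h * mA)) + params.mu_A
            return np.concatenate([dP, dA])

        return rhs
    if model == "2d":
        return lambda t, y: twod_rhs(np.maximum(y, 0.0), params)
    if model == "1d":
        return lambda t, y: np.array([oned_rhs(max(float(y[0]), 0.0), params)])
    raise ValueError(f"unknown model tag {model!r}")


def integrate(model: ModelTag, params, net: BipartiteNetwork | None,
              init: np.ndarray | float, *, max_steps: int = MAX_STEPS,
              tol: float = SETTLE_TOL, window: int = SETTLE_WINDOW,
              stop_when_steady: bool = True) -> Trajectory:
    """Integrate a model to (at most) ``max_steps`` unit time steps.

    Adaptive stiff-safe integration internally (LSODA), sampled at unit
    steps; abundances are clipped at zero at every sample (populations
    cannot be negative).  When ``stop_when_steady`` the integration halts as
    soon as every state variable has changed by less than ``tol`` per step
    over ``window`` consecutive steps.
    """
    y0 = np.atleast_1d(np.asarray(init, dtype=float)).copy()
    if np.any(y0 < 0):
        raise ValueError("initial abundances must be nonnegative")
    rhs = _rhs_for(model, params, net)

    chunk = max(window + 1, 10)
    times = [0.0]
    states = [np.maximum(y0, 0.0)]
    t = 0
    quiet = 0  # consecutive steps with change < tol
    while t < max_steps:
        t_next = min(t + chunk, max_steps)
        t_eval = np.arange(t + 1, t_next + 1, dtype=float)
        sol = solve_ivp(rhs, (float(t), float(t_next)), states[-1], method="LSODA",
                        t_eval=t_eval, rtol=1e-8, atol=1e-10)
        if not sol.success:
            partial = Trajectory(np.array(times), np.array(states), model)
            raise IntegrationError(f"integrator failed at t={t}: {sol.message}", partial)
        for k in range(sol.y.shape[1]):
            y = np.maximum(sol.y[:, k], 0.0)
            delta = np.max(np.abs(y - states[-1]))
            quiet = quiet + 1 if delta < tol else 0
            times.append(sol.t[k])
            states.append(y)
            if stop_when_steady and quiet >= window:
                return Trajectory(np.array(times), np.array(states), model)
        t = t_next
    return Trajectory(np.array(times), np.array(states), model)


def detect_steady(traj: Trajectory, tol: float = SETTLE_TOL,
                  window: int = SETTLE_WINDOW,
                  max_steps: int = MAX_STEPS) -> tuple[int, bool]:
    """Settling time: the first sampled step from which every species'
    abundance changes by less than ``tol`` over each of the next ``window``
    steps.  Returns ``(ST, settled)``; an unsettled trajectory gets the
    sentinel ``ST = max_steps`` with ``settled=False``.
    """
    diffs = np.max(np.abs(np.diff(traj.states, axis=0)), axis=1)
    small = diffs < tol
    run = 0
    # scan from the end: position t qualifies if steps t..t+window-1 are all quiet
    qualifies = np.zeros(len(small) + 1, dtype=bool)
    for i in range(len(small) - 1, -1, -1):
        run = run + 1 if small[i] else 0
        if run >= window:
            qualifies[i] = True
    idx = np.flatnonzero(qualifies)
    if idx.size:
        return int(traj.times[idx[0]]), True
    return max_steps, False


def criteria(traj: Trajectory, *, n_reference: int,
             extinct_threshold: float = EXTINCT_THRESHOLD,
             weights: Sequence[float] | None = None,
             tol: float = SETTLE_TOL, window: int = SETTLE_WINDOW,
             max_steps: int = MAX_STEPS,
             abundance_stat: Literal["mean", "sum"] = "mean") -> CriteriaRecord:
    """Abundance X, settling time ST and persistence P of a trajectory.

    A state entry survives if its final abundance exceeds
    ``extinct_threshold``.  ``weights`` maps state entries to species counts
    for the reduced models (e.g. the 2-D plant compartment stands for all
    currently present plants); the per-species model uses unit weights.
    ``P`` is the surviving species count over ``n_reference`` (the intact
    network's species count); ``X`` the mean (or total) final abundance over
    surviving entries, zero when nothing survives.
    """
    final = traj.final_state
    w = np.ones(final.shape[0]) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != final.shape:
        raise ValueError("weights length must match state dimension")
    alive = final > extinct_threshold
    persistence = float(w[alive].sum() / n_reference) if n_reference else 0.0
    if alive.any():
        X = float(final[alive].sum() if abundance_stat == "sum" else final[alive].mean())
    else:
        X = 0.0
    st, settled = detect_steady(traj, tol=tol, window=window, max_steps=max_steps)
    return CriteriaRecord(abundance_X=X, settling_time_ST=st, settled=settled,
                          persistence_P=min(persistence, 1.0))
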