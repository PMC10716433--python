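"""Bipartite mutualistic network data model, I/O and topological metrics.

The central object is :class:`BipartiteNetwork`: an unweighted, undirected
bipartite species-interaction network with plants as rows and pollinators as
columns of a binary incidence matrix.  All topology used by the restoration
framework lives here: the (S, A, C, NODF) attribute summary, species
centralities on the bipartite graph, one-mode projections and the
nearest-neighbour weighted degree ``beta_eff`` that parameterises the
one-dimensional reduced model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

Side = Literal["plants", "pollinators"]
CentralityMeasure = Literal["degree", "closeness", "betweenness"]

__all__ = [
    "BipartiteNetwork",
    "NetworkAttributes",
    "CentralityScores",
    "ProjectedNetwork",
    "attributes",
    "nodf",
    "centrality",
    "project",
    "beta_eff",
    "read_incidence",
    "write_incidence",
]


class IsolatedSpeciesError(ValueError):
    """Raised when a network under construction contains a species with no partners."""


class FormatError(ValueError):
    """Raised when an incidence file violates the expected dialect."""


@dataclass(frozen=True)
class BipartiteNetwork:
    """Unweighted, undirected bipartite species-interaction network.

    Parameters
    ----------
    plant_labels : tuple of str
        Ordered plant species identifiers (rows of ``incidence``).
    pollinator_labels : tuple of str
        Ordered pollinator species identifiers (columns of ``incidence``).
    incidence : ndarray of shape (n_plants, n_pollinators)
        Binary matrix; entry ``(i, j)`` is 1 iff plant *i* and pollinator *j*
        interact.

    Notes
    -----
    Fully collapsed networks (zero species on one or both sides) are legal:
    they arise naturally at the end of an extinction cascade.  Among the
    species that *are* present, isolated ones are forbidden — under obligate
    mutualism a species with no partners is extinct by definition.
    """

    plant_labels: tuple[str, ...]
    pollinator_labels: tuple[str, ...]
    incidence: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        inc = np.asarray(self.incidence)
        if inc.ndim != 2:
            raise ValueError("incidence must be a 2-D matrix")
        if inc.shape != (len(self.plant_labels), len(self.pollinator_labels)):
            raise ValueError(
                f"incidence shape {inc.shape} does not match label counts "
                f"({len(self.plant_labels)}, {len(self.pollinator_labels)})"
            )
        if inc.size and not np.isin(inc, (0, 1)).all():
            raise ValueError("incidence entries must be 0 or 1")
        inc = inc.astype(np.int8, copy=True)
        inc.setflags(write=False)
        object.__setattr__(self, "incidence", inc)
        object.__setattr__(self, "plant_labels", tuple(str(x) for x in self.plant_labels))
        object.__setattr__(
            self, "pollinator_labels", tuple(str(x) for x in self.pollinator_labels)
        )
        labels = self.plant_labels + self.pollinator_labels
        if len(set(labels)) != len(labels):
            raise ValueError("species labels must be unique across both sides")
        if inc.size:
            empty_rows = np.flatnonzero(inc.sum(axis=1) == 0)
            empty_cols = np.flatnonzero(inc.sum(axis=0) == 0)
            if empty_rows.size or empty_cols.size:
                bad = [self.plant_labels[i] for i in empty_rows] + [
                    self.pollinator_labels[j] for j in empty_cols
                ]
                raise IsolatedSpeciesError(
                    f"isolated species (no mutualistic partner): {bad}"
                )
        elif len(self.plant_labels) and len(self.pollinator_labels):
            # one side has labels but zero columns/rows => everything isolated
            raise IsolatedSpeciesError("non-empty side with no possible partners")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_plants(self) -> int:
        return len(self.plant_labels)

    @property
    def m_pollinators(self) -> int:
        return len(self.pollinator_labels)

    @property
    def n_links(self) -> int:
        return int(self.incidence.sum())

    @property
    def species(self) -> tuple[str, ...]:
        """All species labels, plants first."""
        return self.plant_labels + self.pollinator_labels

    def is_empty(self) -> bool:
        return self.n_plants == 0 or self.m_pollinators == 0

    def degrees(self) -> dict[str, int]:
        """Number of mutualistic partners of every species."""
        row = self.incidence.sum(axis=1)
        col = self.incidence.sum(axis=0)
        out = {lab: int(d) for lab, d in zip(self.plant_labels, row)}
        out.update({lab: int(d) for lab, d in zip(self.pollinator_labels, col)})
        return out

    def side_of(self, label: str) -> Side:
        if label in self.plant_labels:
            return "plants"
        if label in self.pollinator_labels:
            return "pollinators"
        raise KeyError(f"unknown species {label!r}")

    def subnetwork(self, keep: Iterable[str], *, allow_isolated: bool = False) -> "BipartiteNetwork":
        """Induced subnetwork on ``keep`` (labels on either side).

        With ``allow_isolated`` the invariant check is skipped — callers such
        as the extinction cascade prune isolated species themselves.
        """
        keep = set(keep)
        ridx = [i for i, p in enumerate(self.plant_labels) if p in keep]
        cidx = [j for j, a in enumerate(self.pollinator_labels) if a in keep]
        inc = self.incidence[np.ix_(ridx, cidx)]
        plants = tuple(self.plant_labels[i] for i in ridx)
        polls = tuple(self.pollinator_labels[j] for j in cidx)
        if allow_isolated:
            obj = object.__new__(BipartiteNetwork)
            object.__setattr__(obj, "plant_labels", plants)
            object.__setattr__(obj, "pollinator_labels", polls)
            inc = inc.astype(np.int8, copy=True)
            inc.setflags(write=False)
            object.__setattr__(obj, "incidence", inc)
            return obj
        return BipartiteNetwork(plants, polls, inc)

    def to_graph(self) -> nx.Graph:
        """The bipartite graph with both sides in one node set."""
        g = nx.Graph()
        g.add_nodes_from(self.plant_labels, bipartite=0)
        g.add_nodes_from(self.pollinator_labels, bipartite=1)
        rows, cols = np.nonzero(self.incidence)
        g.add_edges_from(
            (self.plant_labels[i], self.pollinator_labels[j]) for i, j in zip(rows, cols)
        )
        return g


@dataclass(frozen=True)
class NetworkAttributes:
    """The (S, A, C, NODF) topology summary used throughout the analyses."""

    size_S: int
    asymmetry_A: float
    connectance_C: float
    nestedness_NODF: float
    n_plants: int
    m_pollinators: int
    L_links: int

    def as_dict(self) -> dict[str, float]:
        return {
            "S": self.size_S,
            "A": self.asymmetry_A,
            "C": self.connectance_C,
            "NODF": self.nestedness_NODF,
        }


@dataclass(frozen=True)
class CentralityScores:
    measure: str
    scores: Mapping[str, float]

    def ranked(self) -> list[str]:
        """Species sorted by descending score, ties broken by label."""
        return sorted(self.scores, key=lambda s: (-self.scores[s], s))


@dataclass(frozen=True)
class ProjectedNetwork:
    """One-mode projection: species of one side, weighted by shared partners."""

    side: Side
    labels: tuple[str, ...]
    adjacency: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=float)
        if adj.shape != (len(self.labels), len(self.labels)):
            raise ValueError("adjacency shape does not match labels")
        if adj.size:
            if not np.allclose(adj, adj.T):
                raise ValueError("projection adjacency must be symmetric")
            if np.any(np.diag(adj) != 0):
                raise ValueError("projection adjacency must have zero diagonal")
        adj.setflags(write=False)
        object.__setattr__(self, "adjacency", adj)

    def binary(self) -> np.ndarray:
        return (self.adjacency > 0).astype(np.int8)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def attributes(net: BipartiteNetwork) -> NetworkAttributes:
    """Size S = n+m, asymmetry A = m/n, connectance C = L/(n*m), and NODF."""
    n, m = net.n_plants, net.m_pollinators
    L = net.n_links
    return NetworkAttributes(
        size_S=n + m,
        asymmetry_A=m / n if n else float("nan"),
        connectance_C=L / (n * m) if n and m else 0.0,
        nestedness_NODF=nodf(net),
        n_plants=n,
        m_pollinators=m,
        L_links=L,
    )


def _nodf_pairs(mat: np.ndarray) -> tuple[float, int]:
    """Sum of paired-overlap percentages over row pairs, and the pair count.

    Rows are compared in decreasing-marginal-total order; a pair in which the
    poorer row's total equals (or exceeds) the richer one's contributes zero
    (the strict decreasing-fill condition).
    """
    totals = mat.sum(axis=1)
    order = np.argsort(-totals, kind="stable")
    mat = mat[order]
    totals = totals[order]
    r = mat.shape[0]
    acc = 0.0
    for i in range(r):
        for j in range(i + 1, r):
            if totals[i] > totals[j] and totals[j] > 0:
                shared = int(np.logical_and(mat[i], mat[j]).sum())
                acc += 100.0 * shared / totals[j]
    return acc, r * (r - 1) // 2


def nodf(net: BipartiteNetwork | np.ndarray) -> float:
    """NODF nestedness of a binary incidence matrix, in [0, 100].

    Mean over all row pairs and all column pairs of the percentage paired
    overlap, where a pair contributes only if the marginal totals strictly
    decrease.  0 is completely non-nested (e.g. one unique partner per
    species), 100 perfectly nested (every poorer species' partner set a
    proper subset of every richer one's, all marginal totals distinct).
    """
    mat = net.incidence if isinstance(net, BipartiteNetwork) else np.asarray(net)
    mat = (mat > 0).astype(np.int8)
    if mat.shape[0] < 2 or mat.shape[1] < 2:
        warnings.warn(
            "NODF undefined with fewer than two species on a side; returning 0",
            stacklevel=2,
        )
        return 0.0
    row_sum, row_pairs = _nodf_pairs(mat)
    col_sum, col_pairs = _nodf_pairs(mat.T)
    return (row_sum + col_sum) / (row_pairs + col_pairs)


def centrality(net: BipartiteNetwork, measure: CentralityMeasure) -> CentralityScores:
    """Species centrality on the full bipartite graph.

    ``degree`` is the raw partner count (row/column sums of the incidence
    matrix).  ``closeness`` is harmonic closeness, which stays finite and
    comparable when a cascade has disconnected the graph (unreachable species
    simply contribute nothing).  ``betweenness`` is shortest-path betweenness;
    normalisation does not affect the induced species ranking.
    """
    if measure == "degree":
        return CentralityScores("degree", {k: float(v) for k, v in net.degrees().items()})
    g = net.to_graph()
    if measure == "closeness":
        # harmonic closeness summed in sorted-label order: the float result is
        # then independent of graph traversal order, so equal scores stay
        # exactly equal and ties break by label, not by accumulated round-off
        scores = {
            u: sum(1.0 / d for _, d in sorted(
                nx.single_source_shortest_path_length(g, u).items()) if d > 0)
            for u in net.species
        }
        return CentralityScores("closeness", scores)
    if measure == "betweenness":
        return CentralityScores(
            "betweenness",
            {k: float(v) for k, v in nx.betweenness_centrality(g, normalized=True).items()},
        )
    raise ValueError(f"unknown centrality measure {measure!r}")


def project(net: BipartiteNetwork, side: Side) -> ProjectedNetwork:
    """One-mode projection onto plants or pollinators.

    Two species of the chosen side are adjacent iff they share at least one
    mutualistic partner; the edge weight counts shared partners.
    """
    inc = net.incidence.astype(np.int64)
    if side == "plants":
        adj = inc @ inc.T
        labels = net.plant_labels
    elif side == "pollinators":
        adj = inc.T @ inc
        labels = net.pollinator_labels
    else:
        raise ValueError(f"unknown side {side!r}")
    adj = adj.astype(float)
    np.fill_diagonal(adj, 0.0)
    return ProjectedNetwork(side=side, labels=labels, adjacency=adj)


def beta_eff(proj: ProjectedNetwork | BipartiteNetwork, *, side: Side = "plants",
             weighted: bool = True) -> float:
    """Nearest-neighbour weighted degree <s^2>/<s> of a one-mode projection.

    With ``s = A·1`` the (weighted) degree vector of the projected adjacency,
    beta_eff = (1' A s)/(1' A 1) = sum(s_i^2)/sum(s_i) — the resilience
    control parameter of the one-dimensional reduced model.  The weighted
    projection (shared-partner counts) is the default; ``weighted=False``
    uses the binarised projection instead.  An edgeless projection yields 0.
    """
    if isinstance(proj, BipartiteNetwork):
        proj = project(proj, side)
    adj = proj.adjacency if weighted else proj.binary().astype(float)
    s = adj.sum(axis=1)
    tot = s.sum()
    if tot == 0:
        return 0.0
    return float(np.dot(s, s) / tot)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

Dialect = Literal["weblife_csv", "edge_list"]


def read_incidence(path: str | Path, dialect: Dialect = "weblife_csv") -> BipartiteNetwork:
    """Read a bipartite network from disk.

    ``weblife_csv`` follows the Web of Life layout: first row holds pollinator
    labels, first column plant labels, numeric cells give interaction counts.
    Any positive cell is binarised (the framework treats networks as
    unweighted).  ``edge_list`` is a two-column TSV ``plant<TAB>pollinator``
    with a header row.
    """
    path = Path(path)
    if dialect == "weblife_csv":
        df = pd.read_csv(path, index_col=0)
        vals = df.to_numpy(dtype=float)
        if np.any(vals < 0):
            raise FormatError(f"{path}: negative interaction values are not allowed")
        inc = (vals > 0).astype(np.int8)
        return BipartiteNetwork(
            tuple(str(x) for x in df.index),
            tuple(str(x) for x in df.columns),
            inc,
        )
    if dialect == "edge_list":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.shape[1] != 2:
            raise FormatError(f"{path}: edge_list requires exactly two columns")
        # an edge list carries no species order, so the dialect fixes a
        # canonical (lexicographic) one; round-trips are exact for networks
        # whose labels are already sorted
        plants = tuple(sorted(set(df.iloc[:, 0])))
        polls = tuple(sorted(set(df.iloc[:, 1])))
        inc = np.zeros((len(plants), len(polls)), dtype=np.int8)
        p_ix = {p: i for i, p in enumerate(plants)}
        a_ix = {a: j for j, a in enumerate(polls)}
        for p, a in df.itertuples(index=False):
            inc[p_ix[p], a_ix[a]] = 1
        return BipartiteNetwork(plants, polls, inc)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_incidence(net: BipartiteNetwork, path: str | Path,
                    dialect: Dialect = "weblife_csv") -> None:
    """Write a network in a dialect that round-trips through `read_incidence`."""
    path = Path(path)
    if dialect == "weblife_csv":
        df = pd.DataFrame(
            net.incidence, index=net.plant_labels, columns=net.pollinator_labels
        )
        df.to_csv(path, lineterminator="\n")
    elif dialect == "edge_list":
        rows, cols = np.nonzero(net.incidence)
        with open(path, "w") as fh:
            fh.write("plant\tpollinator\n")
            for i, j in zip(rows, cols):
                fh.write(f"{net.plant_labels[i]}\t{net.pollinator_labels[j]}\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
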