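"""Protein–protein interaction network construction and topology analysis.

The PPI network is a weighted, undirected graph over gene symbols.  Edge
weight counts distinct supporting interaction records; supporting PMIDs are
retained per edge.  Analyses cover average degree, the degree distribution
and its power-law character (scale-freeness), betweenness centrality, hub
ranking, and Louvain community detection.

Power-law assessment
--------------------
The degree distribution is fitted with the discrete maximum-likelihood
estimator for :math:`p(k) \\propto k^{-\\alpha}` on the tail :math:`k \\ge
k_{min}`, selecting :math:`k_{min}` by minimizing the Kolmogorov–Smirnov
distance between the empirical and fitted tail CDFs, with at least
``min_tail`` observations in the tail.  The distribution is judged plausibly
power-law when the optimal KS distance falls below ``ks_threshold`` *and*
the fitted exponent lies within the range observed for empirical scale-free
networks (:math:`\\alpha \\le` ``alpha_max``); steeply decaying tails such as
the Poisson degrees of an Erdős–Rényi graph can achieve small KS distances
on a short tail but only with implausibly large exponents.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import zeta

__all__ = [
    "PpiNetwork",
    "PowerLawFit",
    "CommunityPartition",
    "EdgeListError",
    "build_network",
    "average_degree",
    "degree_histogram",
    "fit_power_law",
    "betweenness",
    "top_hubs",
    "detect_communities",
]


class EdgeListError(ValueError):
    """A row of an edge-list file could not be parsed."""


@dataclass
class PpiNetwork:
    """Weighted undirected PPI graph; thin wrapper over ``networkx.Graph``.

    Edge attributes: ``weight`` (number of distinct supporting records) and
    ``pmids`` (sorted tuple of supporting PMIDs).
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degrees(self) -> dict[str, int]:
        return dict(self.graph.degree())

    def isolates(self) -> list[str]:
        return sorted(nx.isolates(self.graph))


def build_network(
    source: str | Path | Iterable[tuple],
    known_symbols: set[str] | None = None,
    allow_self_loops: bool = False,
) -> PpiNetwork:
    """Build a PPI network from an edge list (TSV path or row iterable).

    The TSV needs columns ``symbol_a`` and ``symbol_b`` and may carry a
    ``pmid`` column.  Duplicate records of the same unordered pair merge into
    one edge with incremented weight and pooled PMIDs.  Self-loops are
    dropped unless ``allow_self_loops``.  When ``known_symbols`` is given,
    rows naming unknown symbols raise :class:`EdgeListError`.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(path)
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        for col in ("symbol_a", "symbol_b"):
            if col not in df.columns:
                raise EdgeListError(f"{path}: missing mandatory column '{col}'")
        rows = [
            (r.symbol_a, r.symbol_b, getattr(r, "pmid", ""))
            for r in df.itertuples(index=False)
        ]
    else:
        rows = [tuple(r) + ("",) * (3 - len(tuple(r))) for r in source]

    g = nx.Graph()
    for n, row in enumerate(rows, start=1):
        if len(row) < 2 or not row[0] or not row[1]:
            raise EdgeListError(f"row {n}: expected two symbols, got {row!r}")
        a, b = str(row[0]).upper(), str(row[1]).upper()
        pmid = int(row[2]) if len(row) > 2 and str(row[2]) else None
        if known_symbols is not None:
            for sym in (a, b):
                if sym not in known_symbols:
                    raise EdgeListError(f"row {n}: unknown symbol {sym}")
        if a == b and not allow_self_loops:
            continue
        if g.has_edge(a, b):
            g[a][b]["weight"] += 1
            if pmid is not None:
                g[a][b]["pmids"] = tuple(sorted(set(g[a][b]["pmids"]) | {pmid}))
        else:
            g.add_edge(a, b, weight=1, pmids=(pmid,) if pmid is not None else ())
    return PpiNetwork(graph=g)


def average_degree(network: PpiNetwork) -> float:
    """Mean number of neighbors, :math:`2|E|/|V|`."""
    if network.n_nodes == 0:
        raise ValueError("average degree is undefined on an empty network")
    return 2.0 * network.n_edges / network.n_nodes


def degree_histogram(network: PpiNetwork) -> dict[int, int]:
    """Map degree k → number of nodes with that degree."""
    hist: dict[int, int] = {}
    for _, d in network.graph.degree():
        hist[d] = hist.get(d, 0) + 1
    return hist


@dataclass(frozen=True)
class PowerLawFit:
    alpha: float
    x_min: int
    ks_distance: float
    n_tail: int
    plausibly_power_law: bool
    success: bool
    message: str = ""


def _discrete_mle(tail: np.ndarray, x_min: int) -> float:
    slogx = float(np.log(tail).sum())
    n = len(tail)

    def nll(a: float) -> float:
        return n * np.log(zeta(a, x_min)) + a * slogx

    res = minimize_scalar(nll, bounds=(1.01, 20.0), method="bounded")
    return float(res.x)


def fit_power_law(
    histogram: Mapping[int, int] | PpiNetwork,
    ks_threshold: float = 0.1,
    alpha_max: float = 5.0,
    min_tail: int = 10,
) -> PowerLawFit:
    """Fit a discrete power law to a degree histogram (degrees >= 1).

    Returns a failure result (``success=False``) instead of raising when the
    histogram is degenerate (fewer than two distinct positive degrees or
    fewer than ``min_tail`` positive-degree nodes).
    """
    if isinstance(histogram, PpiNetwork):
        histogram = degree_histogram(histogram)
    degrees: list[int] = []
    for k, n_k in histogram.items():
        if k >= 1:
            degrees.extend([int(k)] * int(n_k))
    xs = np.sort(np.asarray(degrees))
    failure = PowerLawFit(
        alpha=float("nan"), x_min=0, ks_distance=float("nan"), n_tail=0,
        plausibly_power_law=False, success=False,
    )
    if len(xs) < min_tail:
        return replace(failure, message=f"only {len(xs)} nodes with degree >= 1")
    if len(np.unique(xs)) < 2:
        return replace(failure, message="degenerate histogram: all degrees equal")

    best: PowerLawFit | None = None
    for x_min in np.unique(xs):
        tail = xs[xs >= x_min]
        if len(tail) < min_tail:
            continue
        alpha = _discrete_mle(tail, int(x_min))
        support = np.arange(x_min, tail.max() + 1)
        pmf = support ** (-alpha) / zeta(alpha, x_min)
        cdf = np.cumsum(pmf)
        ecdf = np.searchsorted(tail, support, side="right") / len(tail)
        ks = float(np.abs(ecdf - cdf).max())
        if best is None or ks < best.ks_distance:
            best = PowerLawFit(
                alpha=alpha,
                x_min=int(x_min),
                ks_distance=ks,
                n_tail=int(len(tail)),
                plausibly_power_law=bool(ks < ks_threshold and alpha <= alpha_max),
                success=True,
            )
    if best is None:
        return replace(failure, message="no admissible x_min with a large enough tail")
    return best


def betweenness(network: PpiNetwork, weighted: bool = False) -> pd.DataFrame:
    """Exact (Brandes) normalized betweenness centrality per node.

    Shortest paths are unweighted by default; with ``weighted=True`` edge
    distances are 1/weight, so strongly supported interactions are shorter.
    Returns a DataFrame indexed by symbol with columns ``degree``,
    ``betweenness`` and ``rank`` (1 = most central; ties break by symbol).
    """
    g = network.graph
    if weighted:
        for _, _, data in g.edges(data=True):
            data["dist"] = 1.0 / data.get("weight", 1)
        bc = nx.betweenness_centrality(g, normalized=True, weight="dist")
    else:
        bc = nx.betweenness_centrality(g, normalized=True)
    nodes = sorted(g.nodes())
    df = pd.DataFrame(
        {
            "degree": [g.degree(n) for n in nodes],
            "betweenness": [bc[n] for n in nodes],
        },
        index=pd.Index(nodes, name="symbol"),
    )
    order = df.sort_values(["betweenness", "symbol"], ascending=[False, True], kind="mergesort").index
    df.loc[order, "rank"] = np.arange(1, len(df) + 1)
    df["rank"] = df["rank"].astype(int)
    return df


def top_hubs(network: PpiNetwork, k: int) -> list[tuple[str, int]]:
    """The k highest-degree nodes as (symbol, degree); ties break by symbol."""
    if k > network.n_nodes:
        raise ValueError(f"k={k} exceeds node count {network.n_nodes}")
    ranked = sorted(network.graph.degree(), key=lambda item: (-item[1], item[0]))
    return ranked[:k]


@dataclass(frozen=True)
class CommunityPartition:
    communities: tuple[frozenset[str], ...]
    modularity: float

    def membership(self) -> dict[str, int]:
        return {node: idx for idx, comm in enumerate(self.communities) for node in comm}

    @property
    def n_communities(self) -> int:
        return len(self.communities)


def detect_communities(network: PpiNetwork, seed: int = 0, resolution: float = 1.0) -> CommunityPartition:
    """Louvain modularity communities; deterministic for a given seed."""
    g = network.graph
    if g.number_of_nodes() == 0:
        return CommunityPartition(communities=(), modularity=0.0)
    comms = nx.community.louvain_communities(g, weight="weight", resolution=resolution, seed=seed)
    comms = sorted((frozenset(c) for c in comms), key=lambda c: sorted(c))
    mod = nx.community.modularity(g, comms, weight="weight", resolution=resolution)
    return CommunityPartition(communities=tuple(comms), modularity=float(mod))
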