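"""The incompatibility interaction network and its Orr-model null.

Merged candidate BDMI regions are nodes; each candidate window pair
contributes an edge between the regions its windows merged into. Under the
classic Orr model of incompatibility accumulation, substitutions arise
sequentially and each new locus interacts with each earlier locus
independently with probability P, which for an observed network is matched
by P = mean degree / (|V| - 1). Simulating that growth process yields null
distributions for topology statistics (max degree, mean shortest-path
length, mean betweenness); an observed network with hub-like architecture
exceeds the null's max degree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as _scistats

from .intervals import IntervalSet, empirical_p, intersect_bp, merge
from .scan import BdmiCallSet

__all__ = [
    "OrrModelParams",
    "NetworkStats",
    "build_graph",
    "degree_vs_me",
    "orr_p_from_graph",
    "simulate_orr_network",
    "network_stats",
    "orr_bootstrap",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OrrModelParams:
    n_nodes: int
    p: float

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("Orr model needs >= 1 node")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"interaction probability must lie in [0, 1], got {self.p}")


@dataclass(frozen=True)
class NetworkStats:
    degree_distribution: np.ndarray
    max_degree: int
    mean_path_length: float
    mean_betweenness: float
    empty: bool = False


def build_graph(calls: BdmiCallSet, matrix=None) -> nx.Graph:
    """Region-level interaction graph from a call set.

    One edge per candidate window pair collapsed to region endpoints;
    parallel edges collapse with multiplicity in the ``weight`` attribute;
    pairs whose two windows merged into the same region are dropped. When an
    AncestryMatrix is given, nodes carry the mean hybrid index of their span
    and a majority-ancestry class label (<0.2 species 0, >0.8 species 1,
    else mixed).
    """
    g = nx.Graph()
    regions = calls.regions
    for ridx, r in enumerate(regions.df.itertuples(index=False)):
        g.add_node(ridx, chrom=r.chrom, start=int(r.start), end=int(r.end),
                   region_degree=int(getattr(r, "score", 0)))
    n_self = 0
    for row in calls.pairs.itertuples(index=False):
        u = calls.window_region[row.window_i]
        v = calls.window_region[row.window_j]
        if u == v:
            n_self += 1
            continue
        if g.has_edge(u, v):
            g[u][v]["weight"] += 1
        else:
            g.add_edge(u, v, weight=1)
    if n_self:
        log.info("build_graph: dropped %d self-pairs after region merging", n_self)
    if matrix is not None:
        for ridx in g.nodes:
            nd = g.nodes[ridx]
            in_span = (
                (matrix.sites["chrom"] == nd["chrom"])
                & (matrix.sites["pos"] >= nd["start"])
                & (matrix.sites["pos"] < nd["end"])
            ).to_numpy()
            sub = matrix.data[:, in_span]
            ok = sub >= 0
            hi = float((sub * ok).sum() / ok.sum()) if ok.any() else float("nan")
            nd["mean_hi"] = hi
            nd["ancestry_class"] = (
                "species0" if hi < 0.2 else "species1" if hi > 0.8 else "mixed"
            )
    return g


@dataclass(frozen=True)
class DegreeMeResult:
    r: float
    p_lower: float
    p_upper: float
    n_points: int
    points: pd.DataFrame
    testable: bool = True


def degree_vs_me(
    graph: nx.Graph,
    barriers: pd.DataFrame,
    reps: int = 1000,
    seed: int = 0,
    method: str = "pearson",
) -> DegreeMeResult:
    """Correlation between region connectivity and local gene-flow reduction.

    Data points are all overlaps between graph regions and barrier-table
    windows: x = the region's graph degree, y = the window's effective
    migration rate m_e. Significance comes from permuting the m_e values
    over the observed degrees ``reps`` times, with one-sided empirical CDF
    p-values floored at 1/reps.
    """
    region_rows = [
        (nd["chrom"], nd["start"], nd["end"]) for _, nd in graph.nodes(data=True)
    ]
    node_ids = list(graph.nodes)
    regions = IntervalSet.from_records(region_rows)
    points = []
    for k, node in enumerate(node_ids):
        nd = graph.nodes[node]
        deg = graph.degree[node]
        hits = barriers[
            (barriers["chrom"] == nd["chrom"])
            & (barriers["start"] < nd["end"])
            & (barriers["end"] > nd["start"])
        ]
        for b in hits.itertuples(index=False):
            points.append((node, deg, float(b.m_e)))
    df = pd.DataFrame(points, columns=["node", "degree", "m_e"])
    if len(df) < 3 or df["degree"].nunique() < 2 or df["m_e"].nunique() < 2:
        return DegreeMeResult(float("nan"), float("nan"), float("nan"), len(df), df, testable=False)
    corr = _scistats.pearsonr if method == "pearson" else _scistats.spearmanr
    x = df["degree"].to_numpy(dtype=float)
    y = df["m_e"].to_numpy(dtype=float)
    obs = float(corr(x, y)[0])
    rng = np.random.default_rng(seed)
    null = np.empty(reps)
    for i in range(reps):
        null[i] = corr(x, rng.permutation(y))[0]
    p_lower, p_upper = empirical_p(null, obs)
    return DegreeMeResult(obs, p_lower, p_upper, len(df), df)


def orr_p_from_graph(graph: nx.Graph) -> OrrModelParams:
    """Match the Orr interaction probability: P = mean degree / (|V| - 1)."""
    n = graph.number_of_nodes()
    if n < 2:
        raise ValueError("Orr P undefined for graphs with fewer than 2 nodes")
    dbar = 2.0 * graph.number_of_edges() / n
    return OrrModelParams(n, dbar / (n - 1))


def simulate_orr_network(params: OrrModelParams, seed: int | np.random.Generator = 0) -> nx.Graph:
    """Sequential-growth Orr network: each new node links to each existing
    node independently with probability P (equivalently G(n, P))."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = params.n_nodes
    g = nx.empty_graph(n)
    if n < 2 or params.p == 0.0:
        return g
    iu = np.triu_indices(n, k=1)
    hit = rng.random(len(iu[0])) < params.p
    g.add_edges_from(zip(iu[0][hit].tolist(), iu[1][hit].tolist()))
    return g


def network_stats(graph: nx.Graph) -> NetworkStats:
    """Degree distribution, max degree, mean shortest-path length over
    reachable ordered pairs, and mean unnormalized betweenness (endpoints
    excluded)."""
    n = graph.number_of_nodes()
    if n == 0:
        return NetworkStats(np.array([], dtype=int), 0, 0.0, 0.0, empty=True)
    degrees = np.array([d for _, d in graph.degree()], dtype=int)
    if graph.number_of_edges() == 0:
        return NetworkStats(degrees, 0, 0.0, 0.0)
    total = 0
    count = 0
    for _, dists in nx.all_pairs_shortest_path_length(graph):
        for d in dists.values():
            if d > 0:
                total += d
                count += 1
    mpl = total / count if count else 0.0
    btw = nx.betweenness_centrality(graph, normalized=False, endpoints=False)
    return NetworkStats(degrees, int(degrees.max()), float(mpl), float(np.mean(list(btw.values()))))


@dataclass(frozen=True)
class OrrBootstrapResult:
    params: OrrModelParams
    observed: NetworkStats
    null_max_degree: np.ndarray
    null_mean_path_length: np.ndarray
    null_mean_betweenness: np.ndarray
    p_values: dict[str, float]  # two-sided empirical p per statistic


def orr_bootstrap(graph: nx.Graph, reps: int = 1000, seed: int = 0) -> OrrBootstrapResult:
    """Null distributions of the topology statistics under the Orr model
    matched to the observed graph's size and mean degree."""
    params = orr_p_from_graph(graph)
    rng = np.random.default_rng(seed)
    obs = network_stats(graph)
    nmd = np.empty(reps)
    nmpl = np.empty(reps)
    nmb = np.empty(reps)
    for i in range(reps):
        st = network_stats(simulate_orr_network(params, rng))
        nmd[i], nmpl[i], nmb[i] = st.max_degree, st.mean_path_length, st.mean_betweenness
    pvals = {}
    for name, null, o in (
        ("max_degree", nmd, obs.max_degree),
        ("mean_path_length", nmpl, obs.mean_path_length),
        ("mean_betweenness", nmb, obs.mean_betweenness),
    ):
        lo, hi = empirical_p(null, o)
        pvals[name] = min(1.0, 2.0 * min(lo, hi))
    return OrrBootstrapResult(params, obs, nmd, nmpl, nmb, pvals)
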