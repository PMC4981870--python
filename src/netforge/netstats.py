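"""Topological diagnostics for functional networks.

Biological co-functional networks are expected to be scale-free-ish
(heavy-tailed degree distribution), far more clustered than degree-
matched random graphs (functional modules), and to separate tight
modules by long paths.  These descriptive checks mirror that validation
style: a log-log regression slope for the degree distribution, average
clustering against a degree-preserving rewired null, and a sampled
shortest-path-length histogram.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .datamodel import DataError

logger = logging.getLogger("netforge")


def to_networkx(net) -> nx.Graph:
    g = nx.Graph()
    for (a, b), w in net.edges.items():
        g.add_edge(a, b, weight=w)
    return g


@dataclass
class TopologyReport:
    degree_hist: dict[int, int]
    powerlaw_exponent: float
    powerlaw_r2: float
    clustering: float
    null_clustering_mean: float
    null_clustering_sd: float
    clustering_fold: float
    path_length_hist: dict[int, int]


def degree_powerlaw(net) -> tuple[float, float]:
    """Log-log regression of the degree distribution.

    Returns (exponent, r^2) where exponent is minus the least-squares
    slope of log10(count) versus log10(degree) over degrees >= 1 with
    nonzero count.  Descriptive only, not a likelihood-based fit.
    """
    g = net if isinstance(net, nx.Graph) else to_networkx(net)
    degrees = [d for _, d in g.degree() if d >= 1]
    hist: dict[int, int] = {}
    for d in degrees:
        hist[d] = hist.get(d, 0) + 1
    if len(hist) < 10:
        raise DataError(f"only {len(hist)} distinct degrees; power-law fit needs >= 10")
    xs = np.log10(sorted(hist))
    ys = np.log10([hist[d] for d in sorted(hist)])
    slope, intercept = np.polyfit(xs, ys, 1)
    pred = slope * xs + intercept
    ss_res = float(np.sum((ys - pred) ** 2))
    ss_tot = float(np.sum((ys - ys.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(-slope), r2


def _mean_local_clustering(g: nx.Graph) -> float:
    """Average of local clustering coefficients (degree < 2 contributes 0)."""
    if g.number_of_nodes() == 0:
        return 0.0
    return float(nx.average_clustering(g, count_zeros=True))


def rewired_null(g: nx.Graph, rng: np.random.Generator) -> nx.Graph:
    """Degree-preserving randomization by double-edge swaps (10 |E| swaps)."""
    null = g.copy()
    n_edges = null.number_of_edges()
    if n_edges < 2 or null.number_of_nodes() < 4:
        return null
    nx.double_edge_swap(
        null,
        nswap=10 * n_edges,
        max_tries=200 * n_edges,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return null


def clustering_vs_null(
    net, n_null: int = 20, seed: int = 0
) -> tuple[float, float, float, float]:
    """Average clustering against a degree-preserving rewired ensemble.

    Returns (clustering, null_mean, null_sd, fold); fold is infinity
    when the null ensemble never closes a triangle.
    """
    g = net if isinstance(net, nx.Graph) else to_networkx(net)
    if max((d for _, d in g.degree()), default=0) < 2:
        raise DataError("network has no node capable of forming a triangle")
    obs = _mean_local_clustering(g)
    rng = np.random.default_rng(seed)
    null_vals = []
    for _ in range(n_null):
        null = rewired_null(g, rng)
        assert dict(null.degree()) == dict(g.degree())
        null_vals.append(_mean_local_clustering(null))
    null_mean = float(np.mean(null_vals))
    null_sd = float(np.std(null_vals))
    fold = obs / null_mean if null_mean > 0 else math.inf
    return obs, null_mean, null_sd, fold


def path_length_profile(net, n_pairs: int = 10000, seed: int = 0) -> dict[int, int]:
    """Histogram of shortest-path lengths over sampled connected pairs.

    ``n_pairs`` node pairs are drawn uniformly (from the largest
    connected component when the graph is disconnected) and their BFS
    distances tallied.
    """
    g = net if isinstance(net, nx.Graph) else to_networkx(net)
    if g.number_of_edges() == 0:
        raise DataError("network has no edges")
    comp = max(nx.connected_components(g), key=lambda c: (len(c), sorted(c)[0]))
    nodes = sorted(comp)
    if len(nodes) < 2:
        raise DataError("largest connected component has < 2 nodes")
    rng = np.random.default_rng(seed)
    hist: dict[int, int] = {}
    sub = g.subgraph(nodes)
    for _ in range(n_pairs):
        i, j = rng.choice(len(nodes), size=2, replace=False)
        length = nx.shortest_path_length(sub, nodes[i], nodes[j])
        hist[length] = hist.get(length, 0) + 1
    return dict(sorted(hist.items()))


def topology_report(
    net, n_null: int = 20, n_pairs: int = 2000, seed: int = 0
) -> TopologyReport:
    """Full diagnostic bundle; power-law stats are NaN when the degree
    spectrum is too narrow to fit."""
    g = to_networkx(net)
    hist: dict[int, int] = {}
    for _, d in g.degree():
        hist[d] = hist.get(d, 0) + 1
    try:
        exponent, r2 = degree_powerlaw(g)
    except DataError:
        exponent, r2 = float("nan"), float("nan")
    clustering, null_mean, null_sd, fold = clustering_vs_null(
        g, n_null=n_null, seed=seed
    )
    paths = path_length_profile(g, n_pairs=n_pairs, seed=seed + 1)
    return TopologyReport(
        degree_hist=dict(sorted(hist.items())),
        powerlaw_exponent=exponent,
        powerlaw_r2=r2,
        clustering=clustering,
        null_clustering_mean=null_mean,
        null_clustering_sd=null_sd,
        clustering_fold=fold,
        path_length_hist=paths,
    )
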