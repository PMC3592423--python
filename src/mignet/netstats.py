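"""Global network properties, scale-free fit and functional-modularity test.

:func:`summarize` computes the headline statistics of an inferred network —
density, average degree, diameter, characteristic path length L, average
clustering coefficient C — together with the expectations for an
Erdos–Renyi random graph of the same size (``L_rand = ln(n)/ln(<k>)``,
``C_rand = <k>/n``), whose comparison with L and C diagnoses the
small-world property, and a hub list (genes with degree above a cutoff,
50 by default).

:func:`powerlaw_fit` fits ``log P(k) ~ log A - gamma * log k`` by least
squares on the observed degree distribution, the standard diagnostic for
scale-free topology; :func:`modularity_test` asks whether a functional gene
set induces fewer connected components than random gene sets of the same
size, via a permutation null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import networkx as nx

__all__ = [
    "NetworkSummary",
    "PowerlawFit",
    "ModularityResult",
    "density",
    "average_degree",
    "summarize",
    "betweenness",
    "degree_distribution",
    "powerlaw_fit",
    "modularity_test",
]


def density(n_nodes: int, n_edges: int) -> float:
    """Fraction of possible edges present: ``2 E / (n (n - 1))``."""
    if n_nodes < 2:
        raise ValueError("density needs at least 2 nodes")
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))


def average_degree(n_nodes: int, n_edges: int) -> float:
    """Mean number of interactions per gene: ``2 E / n``."""
    if n_nodes < 1:
        raise ValueError("average degree needs at least 1 node")
    return 2.0 * n_edges / n_nodes


@dataclass
class NetworkSummary:
    n_nodes: int
    n_edges: int
    density: float
    average_degree: float
    diameter: int | None
    path_length: float | None
    clustering: float
    L_rand: float | None
    C_rand: float
    hubs: list[tuple[str, int]]

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "density": self.density,
            "average_degree": self.average_degree,
            "diameter": self.diameter,
            "path_length": self.path_length,
            "clustering": self.clustering,
            "L_rand": self.L_rand,
            "C_rand": self.C_rand,
            "hubs": [list(h) for h in self.hubs],
        }


def summarize(net: nx.Graph, hub_min_degree: int = 50) -> NetworkSummary:
    """Global properties of an undirected network.

    Path-based statistics (characteristic path length L, diameter) are
    taken over connected node pairs only, so disconnected networks are
    summarised by their components (dominated by the giant component in
    practice); an edgeless network reports them as ``None``.  Nodes of
    degree < 2 contribute a clustering coefficient of 0.
    """
    n = net.number_of_nodes()
    e = net.number_of_edges()
    if n < 2:
        raise ValueError("summary needs at least 2 nodes")

    total_len = 0
    n_pairs = 0
    diam = 0
    for source, lengths in nx.all_pairs_shortest_path_length(net):
        for target, d in lengths.items():
            if target == source:
                continue
            total_len += d
            n_pairs += 1
            diam = max(diam, d)
    has_paths = n_pairs > 0
    avg_deg = average_degree(n, e)
    return NetworkSummary(
        n_nodes=n,
        n_edges=e,
        density=density(n, e),
        average_degree=avg_deg,
        diameter=diam if has_paths else None,
        path_length=total_len / n_pairs if has_paths else None,
        clustering=nx.average_clustering(net) if e else 0.0,
        L_rand=(math.log(n) / math.log(avg_deg)) if avg_deg > 1 else None,
        C_rand=avg_deg / n,
        hubs=sorted(
            ((str(v), d) for v, d in net.degree() if d >= hub_min_degree),
            key=lambda vd: (-vd[1], vd[0]),
        ),
    )


def betweenness(net: nx.Graph, normalized: bool = False) -> dict:
    """Unweighted shortest-path betweenness centrality per node.

    Unnormalized by default: the centre of a k-leaf star scores
    ``k * (k - 1) / 2`` (one count per connected pair routed through it).
    """
    return nx.betweenness_centrality(net, normalized=normalized, weight=None)


def degree_distribution(net: nx.Graph) -> tuple[np.ndarray, np.ndarray]:
    """Observed degrees k (> 0 nodes) and fraction of nodes P(k) at each."""
    degrees = np.array([d for _, d in net.degree()], dtype=int)
    ks, counts = np.unique(degrees, return_counts=True)
    return ks, counts / degrees.size


@dataclass
class PowerlawFit:
    gamma: float
    logA: float
    r_squared: float
    n_points: int
    flat: bool                     # near-zero slope: not scale-free
    cumulative_gamma: float
    cumulative_logA: float

    def to_dict(self) -> dict:
        return {
            "gamma": self.gamma, "logA": self.logA,
            "r_squared": self.r_squared, "n_points": self.n_points,
            "flat": self.flat, "cumulative_gamma": self.cumulative_gamma,
            "cumulative_logA": self.cumulative_logA,
        }


def powerlaw_fit(
    net: nx.Graph, k_min: int = 1, flat_slope: float = 0.5
) -> PowerlawFit:
    """Least-squares scale-free fit of the degree distribution.

    Fits a straight line to ``(log k, log P(k))`` over observed degrees
    ``k >= k_min`` with ``P(k) > 0`` (zero-count degrees are skipped, not
    interpolated) and returns the slope magnitude ``gamma``.  Points are
    weighted by the square root of their node counts — the sampling
    variance of a log-proportion scales inversely with its count, so this
    keeps the noisy one-node tail from flattening the fit.  A parallel fit
    of the cumulative distribution ``P(K >= k)`` is returned as a
    robustness check.  ``flat`` flags fits with ``gamma < flat_slope``,
    i.e. distributions with no power-law decay.
    """
    ks, pk = degree_distribution(net)
    sel = ks >= max(k_min, 1)
    ks, pk = ks[sel], pk[sel]
    if ks.size < 3:
        raise ValueError(
            f"power-law fit needs >= 3 distinct degrees >= {k_min}, got {ks.size}"
        )
    n_total = sum(1 for _ in net.nodes())
    w = np.sqrt(pk * n_total)
    x, y = np.log(ks.astype(float)), np.log(pk)
    slope, intercept = np.polyfit(x, y, 1, w=w)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0

    ck = np.array([pk[ks >= k].sum() for k in ks])
    cslope, cintercept = np.polyfit(x, np.log(ck), 1, w=w)

    gamma = abs(float(slope))
    return PowerlawFit(
        gamma=gamma, logA=float(intercept), r_squared=r2, n_points=int(ks.size),
        flat=gamma < flat_slope,
        cumulative_gamma=abs(float(cslope)), cumulative_logA=float(cintercept),
    )


@dataclass
class ModularityResult:
    gene_set_size: int
    observed_components: int
    null_components: np.ndarray = field(repr=False)
    p_value: float

    @property
    def n_shuffles(self) -> int:
        return int(self.null_components.shape[0])


def modularity_test(
    net: nx.Graph, genes: set, shuffles: int = 102_400, seed: int = 0
) -> ModularityResult:
    """Permutation test for functional modularity of a gene set.

    The statistic is the number of connected components of the subgraph
    induced by the gene set (small for a tightly interacting module; nodes
    isolated within the set each count as one component).  The null draws
    random node sets of the same size from the network — distributionally
    identical to relabelling all nodes by a random permutation — and the
    empirical p-value ``(1 + #{null <= observed}) / (1 + shuffles)`` asks
    how often chance alone produces as few components.
    """
    genes = set(genes)
    missing = sorted(g for g in genes if g not in net)
    if missing:
        raise ValueError(f"genes absent from network: {missing}")
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    if shuffles < 1:
        raise ValueError("need at least 1 shuffle for a p-value")

    observed = nx.number_connected_components(net.subgraph(genes))
    nodes = np.array(sorted(net.nodes()), dtype=object)
    rng = np.random.default_rng(seed)
    null = np.empty(shuffles, dtype=int)
    size = len(genes)
    for s in range(shuffles):
        pick = nodes[rng.choice(nodes.size, size=size, replace=False)]
        null[s] = nx.number_connected_components(net.subgraph(pick))
    p = (1 + int(np.sum(null <= observed))) / (1 + shuffles)
    return ModularityResult(
        gene_set_size=size, observed_components=observed,
        null_components=null, p_value=p,
    )
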