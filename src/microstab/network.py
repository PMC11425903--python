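"""Signed co-occurrence networks and their topology statistics.

Edges carry the sign of the underlying correlation and |r| as weight; all
topology statistics below are sign-blind (computed on the unsigned graph),
with the positive-edge fraction reported separately.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .rmt import CorrelationMatrix

logger = logging.getLogger(__name__)

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62


@dataclass
class SignedNetwork:
    """Undirected taxon graph; edge attrs ``sign`` (+1/-1) and ``weight`` (|r|)."""

    graph: nx.Graph
    threshold: float | None = None

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def positive_edge_fraction(self) -> float:
        if self.n_edges == 0:
            return float("nan")
        pos = sum(1 for _, _, d in self.graph.edges(data=True) if d["sign"] > 0)
        return pos / self.n_edges


@dataclass
class TopologyRecord:
    n: int
    L: int
    avgK: float  # 2L/n
    avgCC: float  # mean local clustering coefficient
    GD: float  # mean shortest-path distance over connected pairs
    CD: float  # degree centralization in [0, 1]
    pos_edge_fraction: float
    sigma: float | None = None  # small-world coefficient
    robustness: float | None = None
    vulnerability: float | None = None


@dataclass
class NodeRole:
    taxon_id: str
    zi: float  # within-module degree z-score
    pi: float  # among-module connectivity
    role: str  # peripheral | module_hub | connector | network_hub


def build_network(corr: CorrelationMatrix, threshold: float) -> SignedNetwork:
    """Adjacency by |r| >= threshold; isolated nodes removed; deterministic."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    values = corr.values
    g = nx.Graph()
    n = len(corr.taxon_ids)
    for i in range(n):
        for j in range(i + 1, n):
            r = values[i, j]
            if abs(r) >= threshold:
                g.add_edge(
                    corr.taxon_ids[i],
                    corr.taxon_ids[j],
                    sign=1 if r > 0 else -1,
                    weight=float(abs(r)),
                )
    if g.number_of_edges() == 0:
        warnings.warn(f"no edge survives threshold {threshold}")
    return SignedNetwork(graph=g, threshold=float(threshold))


def _mean_distance_within_components(g: nx.Graph) -> float:
    """Mean shortest-path length over connected pairs, pooled across components."""
    total, pairs = 0.0, 0
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        k = sub.number_of_nodes()
        if k < 2:
            continue
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            total += sum(dists.values())
        pairs += k * (k - 1)
    return total / pairs if pairs else float("nan")


def degree_centralization(g: nx.Graph) -> float:
    """Freeman degree centralization: sum(k_max - k_i) / ((n-1)(n-2))."""
    n = g.number_of_nodes()
    if n < 3:
        raise ValueError("degree centralization needs at least three nodes")
    degrees = np.array([d for _, d in g.degree()])
    return float((degrees.max() - degrees).sum() / ((n - 1) * (n - 2)))


def topology(net: SignedNetwork) -> TopologyRecord:
    """n, L, avgK, avgCC, GD, CD and the positive-edge fraction."""
    g = net.graph
    n, L = g.number_of_nodes(), g.number_of_edges()
    if n < 2:
        raise ValueError("topology needs at least two nodes")
    return TopologyRecord(
        n=n,
        L=L,
        avgK=2.0 * L / n,
        avgCC=nx.average_clustering(g),
        GD=_mean_distance_within_components(g),
        CD=degree_centralization(g) if n >= 3 else 0.0,
        pos_edge_fraction=net.positive_edge_fraction(),
    )


def small_world_sigma(net: SignedNetwork, n_random: int = 50, seed: int = 0) -> float:
    """Small-world coefficient sigma = (C/C_rand) / (GD/GD_rand).

    The null ensemble is ``n_random`` Erdos-Renyi G(n, L) graphs matched to
    the largest connected component's node and edge counts. sigma > 1
    indicates small-world structure (clustering above random at comparable
    path length).
    """
    if n_random < 10:
        raise ValueError("need at least 10 random graphs for a stable null")
    g = net.graph
    comp = max(nx.connected_components(g), key=len)
    if len(comp) < 4:
        raise ValueError("largest component too small for sigma")
    sub = g.subgraph(comp)
    n, L = sub.number_of_nodes(), sub.number_of_edges()
    c_obs = nx.average_clustering(sub)
    gd_obs = _mean_distance_within_components(sub)
    rng = np.random.default_rng(seed)
    c_rand, gd_rand = [], []
    for _ in range(n_random):
        r = nx.gnm_random_graph(n, L, seed=int(rng.integers(2 ** 31)))
        c_rand.append(nx.average_clustering(r))
        if not nx.is_connected(r):
            logger.debug("sigma null graph disconnected; GD on largest component")
        gd_rand.append(_mean_distance_within_components(r))
    c_bar, gd_bar = np.mean(c_rand), np.mean(gd_rand)
    if c_bar == 0 or gd_bar == 0 or gd_obs == 0:
        return float("nan")
    return float((c_obs / c_bar) / (gd_obs / gd_bar))


def detect_modules(net: SignedNetwork, seed: int = 0) -> dict:
    """Greedy modularity maximization on the unsigned graph.

    Deterministic: the algorithm itself has no randomness and module IDs
    are assigned in order of each community's smallest node label (``seed``
    is accepted for interface symmetry with the other stochastic stages).
    Also records membership on the graph's node attributes.
    """
    g = net.graph
    if g.number_of_nodes() < 2:
        raise ValueError("module detection needs at least two nodes")
    communities = nx.algorithms.community.greedy_modularity_communities(g)
    communities = sorted((sorted(c) for c in communities), key=lambda c: c[0])
    membership = {}
    for mid, comm in enumerate(communities):
        for node in comm:
            membership[node] = mid
    nx.set_node_attributes(net.graph, membership, "module")
    return membership


def zi_pi(net: SignedNetwork, membership: dict) -> list[NodeRole]:
    """Within-module degree z-score (Zi) and among-module connectivity (Pi).

    Zi = (kappa_i - mean kappa over the node's module) / sd; sd = 0 maps to
    Zi = 0. Pi = 1 - sum_s (kappa_is / k_i)^2 over modules s. Roles follow
    the 2.5 / 0.62 grid: module hubs (Zi >= 2.5, Pi < 0.62), connectors
    (Zi < 2.5, Pi >= 0.62), network hubs (both, the keystone class),
    peripheral otherwise.
    """
    g = net.graph
    missing = [v for v in g.nodes if v not in membership]
    if missing:
        raise ValueError(f"membership missing for nodes: {missing[:5]}")
    # within-module degree per node
    kappa = {v: 0 for v in g.nodes}
    for u, v in g.edges:
        if membership[u] == membership[v]:
            kappa[u] += 1
            kappa[v] += 1
    by_module: dict = {}
    for v in g.nodes:
        by_module.setdefault(membership[v], []).append(kappa[v])
    stats = {
        m: (np.mean(vals), np.std(vals))
        for m, vals in by_module.items()
    }
    roles = []
    for v in sorted(g.nodes):
        mean_k, sd_k = stats[membership[v]]
        zi = (kappa[v] - mean_k) / sd_k if sd_k > 0 else 0.0
        k_i = g.degree(v)
        if k_i == 0:
            pi = 0.0
        else:
            per_module: dict = {}
            for u in g.neighbors(v):
                per_module[membership[u]] = per_module.get(membership[u], 0) + 1
            pi = 1.0 - sum((c / k_i) ** 2 for c in per_module.values())
        if zi >= ZI_THRESHOLD and pi >= PI_THRESHOLD:
            role = "network_hub"
        elif zi >= ZI_THRESHOLD:
            role = "module_hub"
        elif pi >= PI_THRESHOLD:
            role = "connector"
        else:
            role = "peripheral"
        roles.append(NodeRole(taxon_id=v, zi=float(zi), pi=float(pi), role=role))
    return roles


def robustness(
    net: SignedNetwork,
    removal_fraction: float = 0.5,
    n_rep: int = 100,
    seed: int = 0,
) -> tuple[float, float]:
    """Random-attack robustness.

    Per repetition, remove ``floor(removal_fraction * n)`` uniformly random
    nodes; robustness is the proportion of surviving nodes that keep at
    least one edge. Returns (mean, sd) over ``n_rep`` repetitions.
    """
    g = net.graph
    nodes = sorted(g.nodes)
    n = len(nodes)
    if n < 4:
        raise ValueError("robustness needs at least four nodes")
    n_remove = int(np.floor(removal_fraction * n))
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_rep):
        removed = set(rng.choice(n, size=n_remove, replace=False))
        keep = [v for i, v in enumerate(nodes) if i not in removed]
        sub = g.subgraph(keep)
        if len(keep) == 0:
            vals.append(0.0)
            continue
        with_edge = sum(1 for v in keep if sub.degree(v) > 0)
        vals.append(with_edge / len(keep))
    return float(np.mean(vals)), float(np.std(vals))


def global_efficiency(g: nx.Graph) -> float:
    """Mean over node pairs of 1/d(u, v); disconnected pairs contribute 0."""
    return nx.global_efficiency(g)


def vulnerability(net: SignedNetwork) -> float:
    """Worst-case relative efficiency loss from a single node removal.

    V = max_i (E - E_i) / E with E the global efficiency and E_i that of
    the graph with node i deleted.
    """
    g = net.graph
    if g.number_of_nodes() < 3:
        raise ValueError("vulnerability needs at least three nodes")
    e_full = global_efficiency(g)
    if e_full == 0:
        return float("nan")
    worst = -np.inf
    for v in sorted(g.nodes):
        sub = g.subgraph([u for u in g.nodes if u != v])
        worst = max(worst, (e_full - global_efficiency(sub)) / e_full)
    return float(worst)


def full_topology(
    net: SignedNetwork,
    n_random: int = 50,
    n_rep: int = 100,
    seed: int = 0,
) -> TopologyRecord:
    """Topology record including sigma, robustness and vulnerability."""
    rec = topology(net)
    try:
        rec.sigma = small_world_sigma(net, n_random=n_random, seed=seed)
    except ValueError:
        rec.sigma = None
    rec.robustness = robustness(net, seed=seed, n_rep=n_rep)[0] if net.n_nodes >= 4 else None
    try:
        rec.vulnerability = vulnerability(net)
    except ValueError:
        rec.vulnerability = None
    return rec
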