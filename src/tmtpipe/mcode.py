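"""Score-thresholded PPI network construction and MCODE complex detection.

The network keeps edges with combined score >= a minimum (0.7 by default,
the high-confidence STRING threshold). Complex detection follows the MCODE
scheme: every vertex is weighted by the product of the highest k-core number
of its closed neighborhood and the density of that core subgraph (vertices
below the degree cutoff weigh 0); complexes grow outward from high-weight
seeds, admitting unassigned neighbors whose weight is at least
seed_weight * (1 - node_score_cutoff); a complex is kept only if its induced
subgraph contains a k-core of order >= the k-core cutoff. The complex score
is density x node count.

The haircut step removes singly-connected material: the complex is reduced
to the 2-edge-connected component containing the seed (bridge edges are
removed and only the seed's side kept). This generalizes the classic
pendant-vertex haircut — a pendant is exactly a single-edge-attached
component — and prevents a single bridge edge from fusing two dense
complexes; nodes stripped by the haircut return to the unassigned pool and
can seed or join later complexes.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .containers import EdgeTable
from .errors import InputError


@dataclass
class MCODEParams:
    """MCODE cutoffs (defaults are the plug-in's defaults)."""

    node_score_cutoff: float = 0.2
    degree_cutoff: int = 4
    k_core: int = 4
    max_depth: int = 100
    haircut: bool = True
    fluff: bool = False
    fluff_density: float = 0.1

    def __post_init__(self):
        if not 0.0 <= self.node_score_cutoff < 1.0:
            raise InputError("node_score_cutoff must lie in [0, 1)")
        if self.degree_cutoff < 1:
            raise InputError("degree_cutoff must be >= 1")
        if self.k_core < 2:
            raise InputError("k_core must be >= 2")


@dataclass
class Cluster:
    """One detected complex."""

    members: tuple          # sorted node names
    n_edges: int
    score: float            # density x node count
    rank: int = 0

    @property
    def n_nodes(self) -> int:
        return len(self.members)


def build_network(edges: EdgeTable, min_score: float = 0.7,
                  node_universe=None) -> nx.Graph:
    """Simple undirected graph of edges with score >= ``min_score``.

    Nodes without surviving edges appear only if listed in
    ``node_universe``.
    """
    G = nx.Graph()
    if node_universe is not None:
        G.add_nodes_from(node_universe)
    f = edges.frame
    keep = f[f["combined_score"] >= min_score]
    for a, b, s in keep.itertuples(index=False):
        G.add_edge(a, b, combined_score=float(s))
    return G


def _core_weight(H: nx.Graph) -> float:
    """Highest core number of H times the density of that core subgraph."""
    if H.number_of_edges() == 0:
        return 0.0
    cores = nx.core_number(H)
    kmax = max(cores.values())
    core_nodes = [v for v, c in cores.items() if c >= kmax]
    C = H.subgraph(core_nodes)
    return kmax * nx.density(C)


def mcode_vertex_weights(G: nx.Graph, params: MCODEParams) -> dict:
    """Deterministic MCODE vertex weights (>= 0)."""
    weights = {}
    for v in G.nodes:
        if G.degree(v) < params.degree_cutoff:
            weights[v] = 0.0
            continue
        closed = set(G[v]) | {v}
        weights[v] = _core_weight(G.subgraph(closed))
    return weights


def _expand(G: nx.Graph, seed, weights: dict, threshold: float,
            assigned: set, max_depth: int) -> set:
    cluster = {seed}
    frontier = [seed]
    depth = 0
    while frontier and depth < max_depth:
        nxt = []
        for v in frontier:
            for u in G[v]:
                if u in cluster or u in assigned:
                    continue
                if weights[u] >= threshold:
                    cluster.add(u)
                    nxt.append(u)
        frontier = nxt
        depth += 1
    return cluster


def _haircut(G: nx.Graph, cluster: set, seed) -> set:
    """Keep the 2-edge-connected component of the cluster containing the seed."""
    if len(cluster) <= 1:
        return cluster
    H = nx.Graph(G.subgraph(cluster))
    H.remove_edges_from(list(nx.bridges(H)))
    for comp in nx.connected_components(H):
        if seed in comp:
            return set(comp)
    return {seed}


def _fluff(G: nx.Graph, cluster: set, assigned: set, density_cutoff: float) -> set:
    extra = set()
    for v in cluster:
        for u in G[v]:
            if u in cluster or u in assigned or u in extra:
                continue
            closed = set(G[u]) | {u}
            if nx.density(G.subgraph(closed)) >= density_cutoff:
                extra.add(u)
    return cluster | extra


def mcode_find_clusters(G: nx.Graph, params: MCODEParams | None = None) -> list:
    """Ranked MCODE complexes of a simple graph.

    Seeds are visited in decreasing weight order (ties by node name); each
    node belongs to at most one complex; complexes whose induced subgraph has
    a highest k-core below ``params.k_core`` are discarded. Ranking is by
    score, then size, with the lexicographically smallest member breaking
    ties. Identical input gives identical output.
    """
    params = params or MCODEParams()
    weights = mcode_vertex_weights(G, params)
    order = sorted(G.nodes, key=lambda v: (-weights[v], str(v)))
    assigned: set = set()
    clusters = []
    for seed in order:
        if seed in assigned or weights[seed] <= 0.0:
            continue
        threshold = weights[seed] * (1.0 - params.node_score_cutoff)
        cluster = _expand(G, seed, weights, threshold, assigned, params.max_depth)
        if params.haircut:
            cluster = _haircut(G, cluster, seed)
        if params.fluff:
            cluster = _fluff(G, cluster, assigned, params.fluff_density)
        H = G.subgraph(cluster)
        if H.number_of_edges() == 0:
            continue
        if max(nx.core_number(H).values()) < params.k_core:
            continue
        assigned |= set(cluster)
        score = nx.density(H) * H.number_of_nodes()
        clusters.append(Cluster(members=tuple(sorted(map(str, cluster))),
                                n_edges=H.number_of_edges(), score=score))
    clusters.sort(key=lambda c: (-c.score, -c.n_nodes, c.members[0] if c.members else ""))
    for i, c in enumerate(clusters, start=1):
        c.rank = i
    return clusters


def clusters_frame(clusters: list):
    """Cluster report rows: rank, score, n_nodes, n_edges, members."""
    import pandas as pd

    return pd.DataFrame([{
        "rank": c.rank, "score": c.score, "n_nodes": c.n_nodes,
        "n_edges": c.n_edges, "members": ";".join(c.members),
    } for c in clusters])
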