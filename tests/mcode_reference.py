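"""Independent brute-force reference for the complex-detection rules.

Implements the same admission semantics as tmtpipe.mcode with its own
primitives (adjacency dicts, pruning-based core decomposition, cycle-based
bridge detection) so it shares no code path with the implementation.
Intended for graphs of at most ~12 nodes.
"""

from itertools import combinations


def _degree(adj, nodes, v):
    return sum(1 for u in adj[v] if u in nodes)


def _max_core(adj, nodes):
    """Highest k such that the k-core of the induced subgraph is non-empty,
    by repeated pruning."""
    nodes = set(nodes)
    best = 0
    k = 1
    while True:
        cur = set(nodes)
        changed = True
        while changed:
            changed = False
            for v in list(cur):
                if _degree(adj, cur, v) < k:
                    cur.remove(v)
                    changed = True
        if not cur:
            return best
        best = k
        k += 1


def _core_nodes(adj, nodes, k):
    cur = set(nodes)
    changed = True
    while changed:
        changed = False
        for v in list(cur):
            if _degree(adj, cur, v) < k:
                cur.remove(v)
                changed = True
    return cur


def _edges_in(adj, nodes):
    return sum(1 for a, b in combinations(sorted(nodes), 2) if b in adj[a])


def _density(adj, nodes):
    n = len(nodes)
    if n < 2:
        return 0.0
    return 2.0 * _edges_in(adj, nodes) / (n * (n - 1))


def _connected(adj, nodes, removed_edge=None):
    nodes = set(nodes)
    if not nodes:
        return True
    start = next(iter(sorted(nodes)))
    seen = {start}
    stack = [start]
    while stack:
        v = stack.pop()
        for u in adj[v]:
            if u not in nodes or u in seen:
                continue
            if removed_edge and {v, u} == set(removed_edge):
                continue
            seen.add(u)
            stack.append(u)
    return seen == nodes


def _component_of(adj, nodes, seed, removed_edges):
    removed = [set(e) for e in removed_edges]
    seen = {seed}
    stack = [seed]
    while stack:
        v = stack.pop()
        for u in adj[v]:
            if u not in nodes or u in seen:
                continue
            if any({v, u} == r for r in removed):
                continue
            seen.add(u)
            stack.append(u)
    return seen


def reference_weights(adj, degree_cutoff):
    weights = {}
    for v in adj:
        if len(adj[v]) < degree_cutoff:
            weights[v] = 0.0
            continue
        closed = set(adj[v]) | {v}
        k = _max_core(adj, closed)
        if k == 0:
            weights[v] = 0.0
            continue
        core = _core_nodes(adj, closed, k)
        weights[v] = k * _density(adj, core)
    return weights


def reference_clusters(edges, nodes, node_score_cutoff=0.2, degree_cutoff=4,
                       k_core=4, max_depth=100, haircut=True):
    """Ranked (score, member frozenset, n_edges) triples."""
    adj = {v: set() for v in nodes}
    for a, b in edges:
        if a != b:
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
    for v in adj:
        adj[v].discard(v)

    weights = reference_weights(adj, degree_cutoff)
    order = sorted(adj, key=lambda v: (-weights[v], str(v)))
    assigned = set()
    found = []
    for seed in order:
        if seed in assigned or weights[seed] <= 0.0:
            continue
        threshold = weights[seed] * (1.0 - node_score_cutoff)
        cluster = {seed}
        frontier = [seed]
        depth = 0
        while frontier and depth < max_depth:
            nxt = []
            for v in frontier:
                for u in sorted(adj[v], key=str):
                    if u in cluster or u in assigned:
                        continue
                    if weights[u] >= threshold:
                        cluster.add(u)
                        nxt.append(u)
            frontier = nxt
            depth += 1
        if haircut and len(cluster) > 1:
            bridges = [
                (a, b) for a, b in combinations(sorted(cluster, key=str), 2)
                if b in adj[a]
                and not _connected(adj, cluster, removed_edge=(a, b))
            ]
            cluster = _component_of(adj, cluster, seed, bridges)
        if _edges_in(adj, cluster) == 0:
            continue
        if _max_core(adj, cluster) < k_core:
            continue
        assigned |= cluster
        score = _density(adj, cluster) * len(cluster)
        found.append((score, frozenset(cluster), _edges_in(adj, cluster)))
    found.sort(key=lambda t: (-t[0], -len(t[1]), sorted(map(str, t[1]))[0]))
    return found
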