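"""Weighted cluster editing of the score graph.

A partition of the variants into clusters pays |w(i,j)| for every positive
edge cut between clusters and for every negative edge kept inside a cluster;
unscored pairs are free.  Minimizing this cost is equivalent to maximizing
the total edge weight inside clusters.  Exact cluster editing is NP-hard, so
production uses a local-search heuristic (greedy agglomeration followed by
single-vertex moves); an exhaustive set-partition search is provided as a
small-instance oracle.
"""

from __future__ import annotations

import heapq
from typing import Dict, List, Sequence

import numpy as np

from .scoring import ScoreGraph

Partition = List[List[int]]

_EPS = 1e-12


def editing_cost(graph: ScoreGraph, partition: Sequence[Sequence[int]]) -> float:
    """Cluster-editing cost of a partition: cut positives + kept negatives."""
    label = _labels(graph.n_vertices, partition)
    cost = 0.0
    for i, j, w in zip(graph.edge_i, graph.edge_j, graph.weight):
        same = label[int(i)] == label[int(j)]
        if w > 0 and not same:
            cost += w
        elif w < 0 and same:
            cost -= w
    return cost


def _labels(n: int, partition: Sequence[Sequence[int]]) -> np.ndarray:
    label = np.full(n, -1, dtype=int)
    for ci, cluster in enumerate(partition):
        for v in cluster:
            if label[v] != -1:
                raise ValueError(f"vertex {v} appears in two clusters")
            label[v] = ci
    if (label == -1).any():
        raise ValueError("partition does not cover all vertices")
    return label


def _canonical(clusters: Dict[int, set]) -> Partition:
    return sorted((sorted(c) for c in clusters.values() if c), key=lambda c: c[0])


def cluster_editing_heuristic(
    graph: ScoreGraph, seed: int = 0, max_passes: int = 50
) -> Partition:
    """Local-search cluster editing: greedy agglomeration + local moves.

    Starting from singletons, repeatedly merges the cluster pair with the
    largest positive total connecting weight; then alternates sweeps of
    single-vertex moves (to the neighboring cluster or a fresh singleton
    with the best strictly positive gain) with whole-cluster merges until
    convergence or ``max_passes`` rounds.  The within-cluster weight never
    decreases, so the editing cost descends monotonically.  Several
    deterministic sweep orders are tried and the lowest-cost partition is
    returned; fully reproducible for a fixed seed.
    """
    n = graph.n_vertices
    adj = graph.adjacency()
    rng = np.random.default_rng(seed)
    starts: List[List[set]] = [[set(c) for c in _greedy_agglomeration(graph, adj)]]
    for _ in range(3):  # pivot constructions seed diverse basins
        order = list(range(n))
        rng.shuffle(order)
        starts.append(_pivot_start(adj, n, order))
    orders = [list(range(n)), list(range(n - 1, -1, -1))]
    shuffled = list(range(n))
    rng.shuffle(shuffled)
    orders.append(shuffled)
    best, best_key = None, None
    seen = set()
    for start in starts:
        start_key = tuple(sorted(tuple(sorted(c)) for c in start))
        if start_key in seen:
            continue
        seen.add(start_key)
        for order in orders:
            partition = _refine(graph, adj, [set(c) for c in start], order, max_passes)
            cost = editing_cost(graph, partition)
            if (
                best_key is None
                or cost < best_key[0] - _EPS
                or (abs(cost - best_key[0]) <= _EPS and len(partition) > best_key[1])
            ):
                best, best_key = partition, (cost, len(partition))
    return best


def _pivot_start(adj, n: int, order: Sequence[int]) -> List[set]:
    """Pivot construction: each unassigned pivot absorbs its positive neighbors."""
    unassigned = set(range(n))
    clusters: List[set] = []
    for v in order:
        if v not in unassigned:
            continue
        cluster = {v}
        unassigned.discard(v)
        for u, w in adj[v].items():
            if u in unassigned and w > 0:
                cluster.add(u)
                unassigned.discard(u)
        clusters.append(cluster)
    return clusters


def _greedy_agglomeration(graph: ScoreGraph, adj) -> Partition:
    """Merge the cluster pair with the largest positive connecting weight."""
    n = graph.n_vertices
    clusters: Dict[int, set] = {v: {v} for v in range(n)}
    cadj: Dict[int, Dict[int, float]] = {v: dict(adj[v]) for v in range(n)}
    heap = []
    for i, j, w in zip(graph.edge_i, graph.edge_j, graph.weight):
        if w > 0:
            heapq.heappush(heap, (-float(w), int(i), int(j)))
    while heap:
        negw, a, b = heapq.heappop(heap)
        w = -negw
        if a not in clusters or b not in clusters:
            continue
        current = cadj[a].get(b)
        if current is None or abs(current - w) > _EPS or current <= 0:
            continue  # stale heap entry
        if len(clusters[b]) > len(clusters[a]):
            a, b = b, a
        clusters[a] |= clusters.pop(b)
        cadj[a].pop(b, None)
        for nb, wb in cadj.pop(b).items():
            if nb == a:
                continue
            merged = cadj[a].get(nb, 0.0) + wb
            cadj[a][nb] = merged
            cadj[nb][a] = merged
            cadj[nb].pop(b, None)
            if merged > 0:
                heapq.heappush(heap, (-merged, min(a, nb), max(a, nb)))
    return _canonical(clusters)


def _refine(
    graph: ScoreGraph,
    adj,
    start_clusters: List[set],
    order: Sequence[int],
    max_passes: int,
) -> Partition:
    """Alternate single-vertex moves and cluster merges, best-gain first."""
    n = graph.n_vertices
    label = np.empty(n, dtype=int)
    members: Dict[int, set] = {}
    for cid, verts in enumerate(start_clusters):
        members[cid] = set(verts)
        for v in verts:
            label[v] = cid
    next_id = len(members)

    for _ in range(max_passes):
        changed = False
        # --- single-vertex moves ---
        for _ in range(max_passes):
            moved = False
            for v in order:
                c = int(label[v])
                conn: Dict[int, float] = {}
                for u, w in adj[v].items():
                    cu = int(label[u])
                    conn[cu] = conn.get(cu, 0.0) + w
                current = conn.get(c, 0.0)
                best_gain, best_target = _EPS, None
                for c2, wsum in conn.items():
                    if c2 == c:
                        continue
                    gain = wsum - current
                    if gain > best_gain:
                        best_gain, best_target = gain, c2
                if -current > best_gain:  # move out into a fresh singleton
                    best_gain, best_target = -current, -1
                if best_target is not None:
                    members[c].discard(v)
                    if not members[c]:
                        del members[c]
                    if best_target == -1:
                        best_target = next_id
                        next_id += 1
                        members[best_target] = set()
                    members[best_target].add(v)
                    label[v] = best_target
                    moved = changed = True
            if not moved:
                break
        # --- whole-cluster merges (vertex moves cannot fuse two clusters) ---
        while True:
            between: Dict[tuple, float] = {}
            for i, j, w in zip(graph.edge_i, graph.edge_j, graph.weight):
                ci, cj = int(label[int(i)]), int(label[int(j)])
                if ci != cj:
                    key = (min(ci, cj), max(ci, cj))
                    between[key] = between.get(key, 0.0) + float(w)
            if not between:
                break
            (ca, cb), gain = max(between.items(), key=lambda kv: (kv[1], -kv[0][0]))
            if gain <= _EPS:
                break
            members[ca] |= members.pop(cb)
            for v in members[ca]:
                label[v] = ca
            changed = True
        if not changed:
            break
    return _canonical(members)


def _set_partitions(items: List[int]):
    """All set partitions, via recursive insertion (Bell-number many)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for sub in _set_partitions(rest):
        for idx in range(len(sub)):
            yield sub[:idx] + [[first] + sub[idx]] + sub[idx + 1 :]
        yield [[first]] + sub


MAX_EXACT_VERTICES = 12


def cluster_editing_exact(graph: ScoreGraph) -> Partition:
    """Globally optimal cluster editing by exhaustive set-partition search.

    Ties in cost are broken toward more (hence smaller) clusters, so an
    all-zero graph yields all singletons.  Refuses instances with more than
    ``MAX_EXACT_VERTICES`` vertices.
    """
    n = graph.n_vertices
    if n > MAX_EXACT_VERTICES:
        raise ValueError(f"exact search limited to n <= {MAX_EXACT_VERTICES}, got {n}")
    if n == 0:
        return []
    wmat = np.zeros((n, n))
    for i, j, w in zip(graph.edge_i, graph.edge_j, graph.weight):
        wmat[int(i), int(j)] = w
        wmat[int(j), int(i)] = w
    best_key = None
    best: Partition | None = None
    for partition in _set_partitions(list(range(n))):
        full = _partition_cost(wmat, partition)
        key = (full, -len(partition))
        if best_key is None or key < best_key:
            best_key, best = key, partition
    assert best is not None
    return sorted((sorted(c) for c in best), key=lambda c: c[0])


def _partition_cost(wmat: np.ndarray, partition: Sequence[Sequence[int]]) -> float:
    n = wmat.shape[0]
    label = np.full(n, -1, dtype=int)
    for ci, cluster in enumerate(partition):
        for v in cluster:
            label[v] = ci
    iu, ju = np.triu_indices(n, k=1)
    w = wmat[iu, ju]
    same = label[iu] == label[ju]
    return float(np.sum(w[(w > 0) & ~same]) - np.sum(w[(w < 0) & same]))
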