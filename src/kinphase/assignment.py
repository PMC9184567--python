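"""Haplotype assignment as weighted interval scheduling on k machines.

Each cluster spans an interval of phasable-variant indices; two clusters can
share a haplotype only if their intervals are disjoint and separated by at
least a full scoring window W (only then is the score graph silent about
their relative placement).  Selecting a maximum-weight conflict-free subset
of clusters and distributing it over the k haplotypes is weighted interval
scheduling on k identical machines, solved exactly as a 0/1 ILP (HiGHS via
scipy).  Conflicts between W-inflated intervals form an interval graph, so
the pairwise conflict constraints are generated as equivalent clique
constraints (one per interval left endpoint and haplotype), and any feasible
selection can be recolored greedily by start index, which is how haplotype
labels are canonicalized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

UNPHASED = 0  # haplotype labels are 1..k; 0 marks an unassigned cluster


@dataclass(frozen=True)
class ClusterInterval:
    """A cluster as a scheduling job: [start, end] in variant-index space."""

    cluster_id: int
    start: int
    end: int
    weight: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("interval start must not exceed end")
        if self.weight < 1:
            raise ValueError("cluster weight (variant count) must be >= 1")


def intervals_from_partition(partition: Sequence[Sequence[int]]) -> List[ClusterInterval]:
    """One job per cluster: span = [min index, max index], profit = size."""
    return [
        ClusterInterval(cid, min(c), max(c), len(c))
        for cid, c in enumerate(partition)
    ]


def is_compatible(a: ClusterInterval, b: ClusterInterval, W: int) -> bool:
    """True iff a and b may share a haplotype: disjoint and >= W apart."""
    return a.end + W <= b.start or b.end + W <= a.start


@dataclass
class Assignment:
    """Cluster -> haplotype map (1..k, or UNPHASED) with its ILP objective."""

    haplotype_of: Dict[int, int]
    objective: float
    exact: bool = True

    def assigned(self) -> Dict[int, int]:
        return {c: h for c, h in self.haplotype_of.items() if h != UNPHASED}


def _conflict_cliques(intervals: Sequence[ClusterInterval], W: int) -> List[List[int]]:
    """Maximal-clique generators of the conflict graph.

    Two jobs conflict iff their W-inflated intervals [start, end + W - 1]
    intersect; for interval graphs every edge lies in a clique anchored at
    some job's start point, so per-point constraints are equivalent to the
    pairwise ones.
    """
    cliques = []
    seen = set()
    for anchor in intervals:
        t = anchor.start
        clique = [
            idx
            for idx, iv in enumerate(intervals)
            if iv.start <= t <= iv.end + W - 1
        ]
        key = tuple(clique)
        if len(clique) > 1 and key not in seen:
            seen.add(key)
            cliques.append(clique)
    return cliques


def solve_assignment(
    intervals: Sequence[ClusterInterval],
    k: int,
    W: int,
    time_limit: Optional[float] = None,
) -> Assignment:
    """Maximum-weight conflict-free assignment of clusters to k haplotypes.

    Maximizes the total weight of assigned clusters subject to: no two
    conflicting clusters on the same haplotype, and each cluster on at most
    one haplotype.  On solver failure a greedy heuristic is used and flagged.
    Haplotype labels are canonical: selected clusters, in order of start
    index, take the lowest compatible label.
    """
    if k < 1:
        raise ValueError("at least one haplotype required")
    n = len(intervals)
    if n == 0:
        return Assignment({}, 0.0)
    weights = np.array([iv.weight for iv in intervals], dtype=float)

    # Variables x[i, j] flattened as i * k + j.
    c = -np.repeat(weights, k)
    rows, cols, data = [], [], []
    r = 0
    for i in range(n):  # each cluster on at most one haplotype
        for j in range(k):
            rows.append(r)
            cols.append(i * k + j)
            data.append(1.0)
        r += 1
    for clique in _conflict_cliques(intervals, W):  # one job per point/machine
        for j in range(k):
            for i in clique:
                rows.append(r)
                cols.append(i * k + j)
                data.append(1.0)
            r += 1
    A = sparse.csr_matrix((data, (rows, cols)), shape=(r, n * k))
    constraint = LinearConstraint(A, -np.inf, np.ones(r))
    options = {}
    if time_limit is not None:
        options["time_limit"] = time_limit
    res = milp(
        c,
        constraints=[constraint],
        integrality=np.ones(n * k),
        bounds=Bounds(0, 1),
        options=options,
    )
    if not res.success:
        warnings.warn(
            f"ILP solver failed ({res.message}); falling back to greedy assignment"
        )
        return _greedy_assignment(intervals, k, W)
    x = np.round(res.x).reshape(n, k)
    selected = [i for i in range(n) if x[i].sum() > 0.5]
    haplotype_of = _canonical_labels(intervals, selected, k, W)
    objective = float(weights[selected].sum())
    return Assignment(haplotype_of, objective, exact=True)


def _canonical_labels(
    intervals: Sequence[ClusterInterval], selected: Sequence[int], k: int, W: int
) -> Dict[int, int]:
    """Greedy interval-graph coloring by start index: lowest free label first."""
    haplotype_of = {iv.cluster_id: UNPHASED for iv in intervals}
    by_machine: Dict[int, List[ClusterInterval]] = {j: [] for j in range(1, k + 1)}
    order = sorted(selected, key=lambda i: (intervals[i].start, intervals[i].end))
    for i in order:
        iv = intervals[i]
        for j in range(1, k + 1):
            if all(is_compatible(iv, other, W) for other in by_machine[j]):
                by_machine[j].append(iv)
                haplotype_of[iv.cluster_id] = j
                break
        else:  # pragma: no cover - selection feasibility guarantees a label
            raise RuntimeError("feasible selection could not be colored with k labels")
    return haplotype_of


def _greedy_assignment(
    intervals: Sequence[ClusterInterval], k: int, W: int
) -> Assignment:
    """Weight-descending greedy fallback (not necessarily optimal)."""
    order = sorted(
        range(len(intervals)), key=lambda i: (-intervals[i].weight, intervals[i].start)
    )
    machines: List[List[ClusterInterval]] = [[] for _ in range(k)]
    selected = []
    for i in order:
        iv = intervals[i]
        for m in machines:
            if all(is_compatible(iv, other, W) for other in m):
                m.append(iv)
                selected.append(i)
                break
    haplotype_of = _canonical_labels(intervals, selected, k, W)
    objective = float(sum(intervals[i].weight for i in selected))
    return Assignment(haplotype_of, objective, exact=False)


MAX_BRUTE_CLUSTERS = 10
MAX_BRUTE_PLOIDY = 4


def brute_force_assignment(
    intervals: Sequence[ClusterInterval], k: int, W: int
) -> float:
    """Optimal objective by exhaustive search (test oracle, small instances).

    Explores all assignments of clusters to {unphased, 1..k} with machine
    labels canonicalized (machines are identical), pruning infeasible
    branches.  Refuses more than 10 clusters or k > 4.
    """
    n = len(intervals)
    if n > MAX_BRUTE_CLUSTERS or k > MAX_BRUTE_PLOIDY:
        raise ValueError("brute force limited to <= 10 clusters and k <= 4")

    best = 0.0

    def recurse(idx: int, machines: List[List[int]], value: float):
        nonlocal best
        if idx == n:
            best = max(best, value)
            return
        iv = intervals[idx]
        recurse(idx + 1, machines, value)  # leave unphased
        used = len(machines)
        for mi in range(min(used + 1, k)):
            if mi < used:
                if not all(
                    is_compatible(iv, intervals[o], W) for o in machines[mi]
                ):
                    continue
                machines[mi].append(idx)
                recurse(idx + 1, machines, value + iv.weight)
                machines[mi].pop()
            else:
                machines.append([idx])
                recurse(idx + 1, machines, value + iv.weight)
                machines.pop()

    recurse(0, [], 0.0)
    return best


@dataclass
class Phasing:
    """Per-variant haplotype placement over the phasable index space."""

    haplotype_of_variant: np.ndarray  # len m, values 0 (unphased) or 1..k
    k: int

    @property
    def phased_fraction(self) -> float:
        m = len(self.haplotype_of_variant)
        return float((self.haplotype_of_variant != UNPHASED).sum() / m) if m else 0.0

    def phased_indices(self) -> np.ndarray:
        return np.flatnonzero(self.haplotype_of_variant != UNPHASED)


def assignment_to_phasing(
    assignment: Assignment,
    partition: Sequence[Sequence[int]],
    n_variants: int,
    k: int,
) -> Phasing:
    """Propagate cluster labels to variants: marker on the assigned haplotype.

    Variants of unassigned clusters remain unphased.
    """
    hap = np.zeros(n_variants, dtype=int)
    for cid, cluster in enumerate(partition):
        h = assignment.haplotype_of.get(cid, UNPHASED)
        if h != UNPHASED:
            for v in cluster:
                hap[v] = h
    return Phasing(haplotype_of_variant=hap, k=k)


def phasing_to_matrix(
    phasing: Phasing, dosages_sprime: Sequence[int] | None = None
) -> np.ndarray:
    """(k, m) minority-allele indicator matrix of the predicted haplotypes.

    Unphased variants get all-zero columns (compare on phased sites only).
    For variants with s'-dosage d >= 2 one copy goes to the assigned
    haplotype and the remaining d-1 copies fill the highest other slots
    deterministically (the pair score localizes only one marker copy).
    """
    k = phasing.k
    m = len(phasing.haplotype_of_variant)
    mat = np.zeros((k, m), dtype=int)
    for v, h in enumerate(phasing.haplotype_of_variant):
        if h == UNPHASED:
            continue
        mat[h - 1, v] = 1
        d = 1 if dosages_sprime is None else int(dosages_sprime[v])
        extra = d - 1
        for slot in range(k, 0, -1):
            if extra <= 0:
                break
            if slot != h:
                mat[slot - 1, v] = 1
                extra -= 1
    return mat
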