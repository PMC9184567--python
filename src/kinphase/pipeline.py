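"""End-to-end phasing pipeline: score -> cluster -> assign -> phase."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .assignment import (
    Assignment,
    Phasing,
    assignment_to_phasing,
    intervals_from_partition,
    solve_assignment,
)
from .clustering import cluster_editing_heuristic
from .scoring import DEFAULT_WINDOW, ScoreGraph, build_score_graph
from .variants import VariantClass


@dataclass
class PhasingRun:
    """All intermediate products of one chromosome-scale phasing run."""

    graph: ScoreGraph
    partition: List[List[int]]
    assignment: Assignment
    phasing: Phasing
    summary: Dict[str, float] = field(default_factory=dict)


def run_phasing(
    depth_major: np.ndarray,
    depth_minor: np.ndarray,
    k: int,
    W: int = DEFAULT_WINDOW,
    classes: Optional[Sequence[VariantClass]] = None,
    seed: int = 0,
    time_limit: Optional[float] = None,
) -> PhasingRun:
    """Phase one chromosome of phasable variants.

    Inputs are the (m, p) majority/minority progeny depth matrices already
    restricted to the phasable index space (see ``select_phasable``).
    """
    m = depth_major.shape[0]
    graph = build_score_graph(depth_major, depth_minor, k, W, classes=classes)
    partition = cluster_editing_heuristic(graph, seed=seed)
    intervals = intervals_from_partition(partition)
    assignment = solve_assignment(intervals, k, W, time_limit=time_limit)
    phasing = assignment_to_phasing(assignment, partition, m, k)
    summary = {
        "n_variants": float(m),
        "n_edges": float(graph.n_edges),
        "n_clusters": float(len(partition)),
        "n_assigned_clusters": float(len(assignment.assigned())),
        "objective": assignment.objective,
        "phased_fraction": phasing.phased_fraction,
    }
    return PhasingRun(
        graph=graph,
        partition=partition,
        assignment=assignment,
        phasing=phasing,
        summary=summary,
    )
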