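"""Sparse windowed score-graph construction.

Scoring every pair of phasable variants grows quadratically, so pairs are
restricted to a window of W intermediate phasable variants and, inside the
window, thinned by a four-phase stride pattern (strides 1, 3, 7, 13) that
scores one in every six window pairs on average.  With the default W = 1500
each interior variant gets exactly 250 scoring partners per direction.

Distances are counted in phasable-variant index space, not base pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import binom

from .inheritance import (
    MAX_SAMPLE_EVIDENCE,
    TransmissionPriors,
    pair_transmission_priors,
    prior_log_odds,
    simplex_nulliplex_priors,
)
from .variants import VariantClass

#: Default scoring window (in phasable variants), a speed/accuracy compromise.
DEFAULT_WINDOW = 1500


@dataclass(frozen=True)
class PairScore:
    """One scored variant pair: symmetric log-likelihood-ratio weight."""

    i: int
    j: int
    w: float


@dataclass
class ScoreGraph:
    """Sparse symmetric graph over phasable variants (0-based vertex ids)."""

    n_vertices: int
    edge_i: np.ndarray
    edge_j: np.ndarray
    weight: np.ndarray
    n_unexplained_samples: int = 0  # progeny skipped: zero likelihood both ways

    @property
    def n_edges(self) -> int:
        return len(self.weight)

    def edges(self) -> List[PairScore]:
        return [
            PairScore(int(i), int(j), float(w))
            for i, j, w in zip(self.edge_i, self.edge_j, self.weight)
        ]

    def adjacency(self) -> List[Dict[int, float]]:
        """Per-vertex neighbor->weight maps (both directions)."""
        adj: List[Dict[int, float]] = [dict() for _ in range(self.n_vertices)]
        for i, j, w in zip(self.edge_i, self.edge_j, self.weight):
            adj[int(i)][int(j)] = float(w)
            adj[int(j)][int(i)] = float(w)
        return adj


def stride_pattern_offsets(W: int) -> List[int]:
    """Offsets (untruncated) selected inside a window of size W.

    Phase 1 takes the ceil(W/24) consecutive offsets after the variant;
    phase 2 continues with stride 3 until ceil(W/12) offsets are selected in
    total; phase 3 adds the next ceil(W/24) offsets with stride 7; phase 4
    continues with stride 13 until the window bound W is passed.
    """
    if W < 1:
        raise ValueError(f"window size must be >= 1, got {W}")
    offsets: List[int] = []
    o = 0
    for _ in range(math.ceil(W / 24)):  # phase 1: stride 1
        o += 1
        if o > W:
            return offsets
        offsets.append(o)
    while len(offsets) < math.ceil(W / 12):  # phase 2: stride 3
        o += 3
        if o > W:
            return offsets
        offsets.append(o)
    for _ in range(math.ceil(W / 24)):  # phase 3: stride 7
        o += 7
        if o > W:
            return offsets
        offsets.append(o)
    while True:  # phase 4: stride 13
        o += 13
        if o > W:
            return offsets
        offsets.append(o)


def scoring_partners(i: int, W: int, m: int) -> List[int]:
    """Offsets o such that (i, i+o) is scored, for variant i of m (1-based).

    The pattern is truncated at the chromosome end: offsets beyond m - i are
    dropped.
    """
    if not 1 <= i <= m:
        raise ValueError(f"variant index {i} outside 1..{m}")
    return [o for o in stride_pattern_offsets(W) if i + o <= m]


def _depth_log_likelihoods(depth_major: np.ndarray, depth_minor: np.ndarray, k: int):
    """(m, p, k+1) array of log P(D | G=g) = Binomial(n, g/k) log-pmf at D(1)."""
    n = depth_major + depth_minor
    out = np.empty(depth_major.shape + (k + 1,))
    with np.errstate(divide="ignore", invalid="ignore"):
        for g in range(k + 1):
            out[..., g] = binom.logpmf(depth_minor, n, g / k)
    return out


def build_score_graph(
    depth_major: np.ndarray,
    depth_minor: np.ndarray,
    k: int,
    W: int = DEFAULT_WINDOW,
    classes: Sequence[VariantClass] | None = None,
    prior_log_ratio: float | None = None,
) -> ScoreGraph:
    """Score all stride-pattern pairs among m phasable variants.

    Parameters
    ----------
    depth_major, depth_minor:
        (m, p) majority/minority read counts, rows in phasable index order.
    classes:
        Per-variant class; defaults to all simplex-nulliplex.  Priors are
        chosen per pair of classes.
    prior_log_ratio:
        Additive placement prior; defaults to log(1/(k-1)).
    """
    depth_major = np.asarray(depth_major)
    depth_minor = np.asarray(depth_minor)
    if depth_major.shape != depth_minor.shape or depth_major.ndim != 2:
        raise ValueError("depth matrices must be two identical (m, p) arrays")
    m = depth_major.shape[0]
    if classes is None:
        class_codes = np.zeros(m, dtype=int)
        class_list = [VariantClass.SIMPLEX_NULLIPLEX]
    else:
        if len(classes) != m:
            raise ValueError("one class per variant required")
        class_list = sorted({c for c in classes}, key=lambda c: c.value)
        code_of = {c: idx for idx, c in enumerate(class_list)}
        class_codes = np.array([code_of[c] for c in classes])
    if prior_log_ratio is None:
        prior_log_ratio = prior_log_odds(k)

    prior_mats = {}
    for a, ca in enumerate(class_list):
        for b, cb in enumerate(class_list):
            if ca == cb == VariantClass.SIMPLEX_NULLIPLEX:
                priors: TransmissionPriors = simplex_nulliplex_priors(k)
            else:
                priors = pair_transmission_priors(k, ca, cb)
            prior_mats[(a, b)] = (priors.log_matrix("same"), priors.log_matrix("diff"))

    LL = _depth_log_likelihoods(depth_major, depth_minor, k)
    covered = (depth_major + depth_minor) > 0  # (m, p)

    edge_i: List[np.ndarray] = []
    edge_j: List[np.ndarray] = []
    weights: List[np.ndarray] = []
    n_unexplained = 0
    for o in stride_pattern_offsets(W):
        if o >= m:
            break
        left = LL[:-o]  # (B, p, k+1)
        right = LL[o:]
        pair_cov = covered[:-o] & covered[o:]  # sample informative for the pair?
        A = left[:, :, :, None] + right[:, :, None, :]  # (B, p, k+1, k+1)
        B = A.shape[0]
        flat = A.reshape(B, A.shape[1], -1)
        w_o = np.full(B, prior_log_ratio)
        codes_l = class_codes[:-o]
        codes_r = class_codes[o:]
        for (a, b), (log_same, log_diff) in prior_mats.items():
            mask = (codes_l == a) & (codes_r == b)
            if not mask.any():
                continue
            with np.errstate(invalid="ignore"):
                ls = logsumexp(flat[mask] + log_same.ravel(), axis=-1)
                ld = logsumexp(flat[mask] + log_diff.ravel(), axis=-1)
                contrib = ls - ld
            # zero coverage at either variant: exactly neutral by construction
            contrib = np.where(pair_cov[mask], contrib, 0.0)
            bad = np.isnan(contrib)  # likelihood 0 under both hypotheses
            n_unexplained += int(bad.sum())
            contrib[bad] = 0.0
            np.clip(contrib, -MAX_SAMPLE_EVIDENCE, MAX_SAMPLE_EVIDENCE, out=contrib)
            w_o[mask] = prior_log_ratio + contrib.sum(axis=1)
        edge_i.append(np.arange(B))
        edge_j.append(np.arange(B) + o)
        weights.append(w_o)

    if weights:
        ei = np.concatenate(edge_i)
        ej = np.concatenate(edge_j)
        ww = np.concatenate(weights)
    else:
        ei = np.empty(0, dtype=int)
        ej = np.empty(0, dtype=int)
        ww = np.empty(0)
    return ScoreGraph(
        n_vertices=m,
        edge_i=ei,
        edge_j=ej,
        weight=ww,
        n_unexplained_samples=n_unexplained,
    )
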