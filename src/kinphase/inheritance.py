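"""Mendelian transmission priors and Bayesian pair scoring.

A progeny of two ploidy-k parents inherits k/2 haplotypes from each parent,
uniformly among the C(k, k/2) possible subsets and independently per parent.
For two marker-carrying variants i and j on the phased parent s', the joint
distribution of inherited minority-allele dosages (n_i, n_j) depends on
whether the markers sit on the same parental haplotype (h_i = h_j) or on
different ones.  These two distributions, L_= ("same") and L_!= ("diff"),
are the priors of the Bayesian pair score: low-coverage progeny allele depths
are explained under either hypothesis via a binomial read-count model, and
the log-likelihood ratio over all progeny (plus the placement prior
log(1/(k-1))) becomes the edge weight of the score graph.

Probabilities are kept as exact `fractions.Fraction` so that the closed-form
simplex-nulliplex priors and the gamete-enumeration path agree bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from math import comb
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
from scipy.special import logsumexp
from scipy.stats import binom

from .variants import VariantClass

Cell = Tuple[int, int]
Distribution = Dict[Cell, Fraction]

#: Cap on one progeny's log-likelihood-ratio contribution.  A single sample
#: whose depths are impossible under one hypothesis (likelihood exactly 0,
#: e.g. minority reads at both variants of a diploid "diff" pair) would
#: otherwise contribute infinite evidence; real panels always carry some
#: residual error, so evidence per sample is bounded.
MAX_SAMPLE_EVIDENCE = 50.0

#: Parental minority dosages (G_s', G_s'') per phasable class.
CLASS_DOSAGES = {
    VariantClass.SIMPLEX_NULLIPLEX: (1, 0),
    VariantClass.SIMPLEX_SIMPLEX: (1, 1),
    VariantClass.DUPLEX_NULLIPLEX: (2, 0),
}


@dataclass(frozen=True)
class TransmissionPriors:
    """Joint distributions of inherited minority dosages (n_i, n_j).

    ``same`` conditions on the two markers sharing a haplotype of s',
    ``diff`` on them lying on disjoint haplotypes.  Only non-zero cells are
    stored; each map sums to 1.
    """

    k: int
    same: Distribution
    diff: Distribution

    def __post_init__(self):
        for name, dist in (("same", self.same), ("diff", self.diff)):
            if sum(dist.values()) != 1:
                raise ValueError(f"{name} prior does not sum to 1")
            if any(p < 0 for p in dist.values()):
                raise ValueError(f"{name} prior has a negative entry")

    def max_dosage(self) -> int:
        return max(max(n for cell in d for n in cell) for d in (self.same, self.diff))

    def log_matrix(self, which: str) -> np.ndarray:
        """Dense (k+1, k+1) matrix of natural-log priors, -inf off support."""
        dist = self.same if which == "same" else self.diff
        mat = np.full((self.k + 1, self.k + 1), -np.inf)
        for (ni, nj), p in dist.items():
            mat[ni, nj] = math.log(p)
        return mat


def _validate_ploidy(k: int) -> None:
    if k < 2 or k % 2 != 0:
        raise ValueError(f"ploidy must be a positive even integer, got {k}")


def simplex_nulliplex_priors(k: int) -> TransmissionPriors:
    """Closed-form priors for a pair of simplex-nulliplex variants.

    With one marker copy each on s' and none on s'':

    * same haplotype: both markers travel together, so
      L_=(1,1) = L_=(0,0) = 1/2 and L_=(0,1) = L_=(1,0) = 0;
    * different haplotypes:
      L_!=(1,1) = L_!=(0,0) = (k/2 - 1) / (2(k - 1)) and
      L_!=(0,1) = L_!=(1,0) = k / (4(k - 1)).
    """
    _validate_ploidy(k)
    half = Fraction(1, 2)
    same: Distribution = {(0, 0): half, (1, 1): half}
    both = Fraction(k // 2 - 1, 2 * (k - 1))
    one = Fraction(k, 4 * (k - 1))
    diff: Distribution = {}
    for cell, p in (((0, 0), both), ((1, 1), both), ((0, 1), one), ((1, 0), one)):
        if p > 0:
            diff[cell] = p
    return TransmissionPriors(k=k, same=same, diff=diff)


def _gamete_pair_distribution(k: int, marked_i, marked_j) -> Distribution:
    """Distribution of (n_i, n_j) over the C(k, k/2) equally likely gametes."""
    set_i, set_j = set(marked_i), set(marked_j)
    counts: Dict[Cell, int] = {}
    total = 0
    for gamete in combinations(range(k), k // 2):
        g = set(gamete)
        cell = (len(set_i & g), len(set_j & g))
        counts[cell] = counts.get(cell, 0) + 1
        total += 1
    return {cell: Fraction(c, total) for cell, c in counts.items()}


def _other_parent_distribution(k: int, d_i: int, d_j: int) -> Distribution:
    """Transmission from s'' with dosages (d_i, d_j), placements uniform.

    s'' carries no information about the s' hypothesis, so its marker
    placements are marginalized uniformly over all C(k,d_i) x C(k,d_j)
    configurations before enumerating its gametes.
    """
    if d_i == 0 and d_j == 0:
        return {(0, 0): Fraction(1)}
    acc: Dict[Cell, Fraction] = {}
    placements = 0
    marked_i = tuple(range(d_i))  # fixed w.l.o.g. by symmetry of gametes
    for marked_j in combinations(range(k), d_j):
        placements += 1
        for cell, p in _gamete_pair_distribution(k, marked_i, marked_j).items():
            acc[cell] = acc.get(cell, Fraction(0)) + p
    return {cell: p / placements for cell, p in acc.items()}


def _convolve(a: Distribution, b: Distribution) -> Distribution:
    out: Dict[Cell, Fraction] = {}
    for (ai, aj), pa in a.items():
        for (bi, bj), pb in b.items():
            cell = (ai + bi, aj + bj)
            out[cell] = out.get(cell, Fraction(0)) + pa * pb
    return out


def priors_by_enumeration(
    k: int,
    dosage_i_on_sprime: int,
    dosage_j_on_sprime: int,
    dosage_i_on_sdp: int,
    dosage_j_on_sdp: int,
    shared_marker_haplotypes: int,
) -> Distribution:
    """Exhaustive-enumeration transmission distribution for one configuration.

    Places ``dosage_i_on_sprime`` and ``dosage_j_on_sprime`` minority copies
    on the haplotypes of s' with exactly ``shared_marker_haplotypes``
    co-located copies, enumerates all C(k, k/2) gametes of s' and
    (independently, placements marginalized uniformly) of s'', and tabulates
    the joint distribution of inherited minority dosages (n_i, n_j).

    Serves both as the production path for simplex-simplex / duplex-nulliplex
    priors and as the test oracle for :func:`simplex_nulliplex_priors`.
    """
    _validate_ploidy(k)
    d_i, d_j = dosage_i_on_sprime, dosage_j_on_sprime
    for d in (d_i, d_j, dosage_i_on_sdp, dosage_j_on_sdp):
        if not 0 <= d <= k:
            raise ValueError(f"dosage {d} outside 0..{k}")
    s = shared_marker_haplotypes
    if not 0 <= s <= min(d_i, d_j) or d_i + d_j - s > k:
        raise ValueError(
            f"shared count {s} inconsistent with dosages ({d_i}, {d_j}) at k={k}"
        )
    marked_i = tuple(range(d_i))
    marked_j = tuple(range(s)) + tuple(range(d_i, d_i + d_j - s))
    sprime = _gamete_pair_distribution(k, marked_i, marked_j)
    other = _other_parent_distribution(k, dosage_i_on_sdp, dosage_j_on_sdp)
    return _convolve(sprime, other)


def pair_transmission_priors(
    k: int, class_i: VariantClass, class_j: VariantClass
) -> TransmissionPriors:
    """Same/diff priors for any pair of phasable variant classes.

    The "same" hypothesis is that the marker haplotype sets of i and j on s'
    share at least one haplotype, "diff" that they are disjoint; inside each
    hypothesis the placements are weighted by their combinatorial
    multiplicity.  For two simplex-nulliplex variants this reduces exactly to
    the closed forms of :func:`simplex_nulliplex_priors`.
    """
    _validate_ploidy(k)
    if class_i not in CLASS_DOSAGES or class_j not in CLASS_DOSAGES:
        raise ValueError("priors are defined for phasable classes only")
    di_p, di_dp = CLASS_DOSAGES[class_i]
    dj_p, dj_dp = CLASS_DOSAGES[class_j]

    def mixture(shared_values) -> Distribution:
        acc: Dict[Cell, Fraction] = {}
        total_weight = 0
        for s in shared_values:
            weight = comb(di_p, s) * comb(k - di_p, dj_p - s)
            if weight == 0:
                continue
            total_weight += weight
            dist = priors_by_enumeration(k, di_p, dj_p, di_dp, dj_dp, s)
            for cell, p in dist.items():
                acc[cell] = acc.get(cell, Fraction(0)) + weight * p
        if total_weight == 0:
            raise ValueError("empty hypothesis: no consistent marker placement")
        return {cell: p / total_weight for cell, p in acc.items()}

    feasible = [
        s for s in range(min(di_p, dj_p) + 1) if di_p + dj_p - s <= k
    ]
    same = mixture([s for s in feasible if s >= 1])
    diff = mixture([s for s in feasible if s == 0])
    return TransmissionPriors(k=k, same=same, diff=diff)


def depth_likelihood(depth: Tuple[int, int], g: int, k: int) -> float:
    """P(D | G = g): binomial read-count likelihood.

    ``depth`` is (majority count D(0), minority count D(1)); given dosage g
    the minority count is Binomial(D(0)+D(1), g/k).  Zero coverage gives
    likelihood 1 for every dosage.
    """
    d0, d1 = depth
    if d0 < 0 or d1 < 0:
        raise ValueError("read counts must be non-negative")
    if not 0 <= g <= k:
        raise ValueError(f"dosage {g} outside 0..{k}")
    return float(binom.pmf(d1, d0 + d1, g / k))


def pair_depth_likelihood(
    depth_i: Tuple[int, int],
    depth_j: Tuple[int, int],
    priors_row: Mapping[Cell, object],
    k: int,
) -> float:
    """P(D_i, D_j | hypothesis): prior-weighted sum over genotype pairs.

    Sums depth_likelihood(D_i | g_i) * depth_likelihood(D_j | g_j) *
    prior(g_i, g_j) over the prior's support; genotype combinations outside
    the support implicitly have prior 0.
    """
    total = 0.0
    for (gi, gj), p in priors_row.items():
        total += (
            depth_likelihood(depth_i, gi, k)
            * depth_likelihood(depth_j, gj, k)
            * float(p)
        )
    return total


def prior_log_odds(k: int) -> float:
    """log P(h_i = h_j) / P(h_i != h_j) under uniform marker placement: log 1/(k-1)."""
    return math.log(1.0 / (k - 1))


def pair_score(
    depths_i: Sequence[Tuple[int, int]],
    depths_j: Sequence[Tuple[int, int]],
    k: int,
    priors: TransmissionPriors | None = None,
    prior_log_ratio: float | None = None,
) -> float:
    """Bayesian log-likelihood-ratio score for one variant pair.

    w = sum_s log P(D_si, D_sj | same) - sum_s log P(D_si, D_sj | diff)
        + log(1/(k-1))

    Positive scores favour the two markers co-occurring on one s' haplotype.
    Progeny with zero coverage at both variants contribute exactly 0; a
    progeny whose depths have likelihood 0 under both hypotheses is skipped.
    All arithmetic is in natural-log space.
    """
    if len(depths_i) != len(depths_j):
        raise ValueError("depth lists must have one entry per progeny each")
    if priors is None:
        priors = simplex_nulliplex_priors(k)
    if prior_log_ratio is None:
        prior_log_ratio = prior_log_odds(k)
    log_same = [(gi, gj, math.log(p)) for (gi, gj), p in priors.same.items()]
    log_diff = [(gi, gj, math.log(p)) for (gi, gj), p in priors.diff.items()]

    w = prior_log_ratio
    for di, dj in zip(depths_i, depths_j):
        if di[0] + di[1] == 0 or dj[0] + dj[1] == 0:
            # Exactly neutral: with no reads at one variant the pair
            # likelihood reduces to the marginal of the other, and marginal
            # transmission does not depend on the same/diff hypothesis.
            continue
        terms_same = [
            lp + _log_depth_likelihood(di, gi, k) + _log_depth_likelihood(dj, gj, k)
            for gi, gj, lp in log_same
        ]
        terms_diff = [
            lp + _log_depth_likelihood(di, gi, k) + _log_depth_likelihood(dj, gj, k)
            for gi, gj, lp in log_diff
        ]
        ls = logsumexp(terms_same)
        ld = logsumexp(terms_diff)
        if np.isneginf(ls) and np.isneginf(ld):
            continue  # unexplainable under both hypotheses; skip sample
        w += float(np.clip(ls - ld, -MAX_SAMPLE_EVIDENCE, MAX_SAMPLE_EVIDENCE))
    return w


def _log_depth_likelihood(depth: Tuple[int, int], g: int, k: int) -> float:
    d0, d1 = depth
    return float(binom.logpmf(d1, d0 + d1, g / k))
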