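"""Phasing error metrics: Hamming rate, switch error rate, wrong genotype rate.

Predicted and true haplotypes are (k, S) allele matrices over the same S
sites (conventionally the sites the prediction actually phased).  Haplotype
labels are arbitrary, so both metrics minimize over label matchings:

* Hamming rate: best single global permutation, fraction of mismatching
  (haplotype, site) cells.
* Switch error rate: a dynamic program over per-site permutations; the
  transition cost between consecutive sites is the number of haplotype
  positions whose matching changes, i.e. how many haplotype strands must be
  re-paired.  At k=2 this reduces to the classical diploid switch error.
  Only sites whose predicted genotype (column dosage) matches the truth can
  be compared.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Sequence, Tuple

import numpy as np


def _check(predicted: np.ndarray, truth: np.ndarray, k: int):
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError(
            f"site-set mismatch: predicted {predicted.shape} vs truth {truth.shape}"
        )
    if predicted.ndim != 2 or predicted.shape[0] != k:
        raise ValueError(f"expected (k, S) = ({k}, S) matrices")
    return predicted, truth


def hamming_rate(predicted: np.ndarray, truth: np.ndarray, k: int) -> float:
    """Minimum over haplotype-label permutations of the allele error fraction."""
    predicted, truth = _check(predicted, truth, k)
    S = predicted.shape[1]
    if S == 0:
        return 0.0
    best = None
    for perm in permutations(range(k)):
        mism = int((predicted != truth[list(perm), :]).sum())
        best = mism if best is None else min(best, mism)
    return best / (k * S)


def switch_error_rate(predicted: np.ndarray, truth: np.ndarray, k: int) -> float:
    """Minimal number of haplotype re-pairings along the sequence, normalized.

    Sites with mismatching genotypes (column dosage) are excluded before the
    dynamic program, as switches are undefined there.  With fewer than two
    comparable sites the rate is 0 by convention.
    """
    predicted, truth = _check(predicted, truth, k)
    match = predicted.sum(axis=0) == truth.sum(axis=0)
    predicted = predicted[:, match]
    truth = truth[:, match]
    S = predicted.shape[1]
    if S < 2:
        return 0.0
    perms = list(permutations(range(k)))
    n_perms = len(perms)
    # transition[a, b] = number of strands re-paired between permutation a and b
    parray = np.array(perms)
    transition = (parray[:, None, :] != parray[None, :, :]).sum(axis=2)

    def consistent(col_pred, col_true) -> np.ndarray:
        # perm a maps predicted strand i -> true strand perms[a][i]
        return np.array(
            [bool((col_pred == col_true[list(perm)]).all()) for perm in perms]
        )

    INF = np.inf
    cost = np.where(consistent(predicted[:, 0], truth[:, 0]), 0.0, INF)
    for t in range(1, S):
        ok = consistent(predicted[:, t], truth[:, t])
        step = (cost[:, None] + transition).min(axis=0)
        cost = np.where(ok, step, INF)
    switches = cost.min()
    if not np.isfinite(switches):  # pragma: no cover - genotype match guarantees
        raise RuntimeError("no consistent permutation path found")
    return float(switches) / (k * (S - 1))


def wrong_genotype_rate(
    predicted_genotypes: Sequence[int], true_genotypes: Sequence[int]
) -> float:
    """Fraction of sites whose predicted dosage differs from the truth."""
    pred = np.asarray(predicted_genotypes)
    true = np.asarray(true_genotypes)
    if pred.shape != true.shape:
        raise ValueError("site-set mismatch between predicted and true genotypes")
    if pred.size == 0:
        return 0.0
    return float((pred != true).mean())


@dataclass(frozen=True)
class PhasingComparison:
    """Bundle of all three error metrics over the predicted-phased sites."""

    n_phased: int
    ser: float
    wgr: float
    hr: float

    def as_percentages(self) -> Tuple[int, float, float, float]:
        return self.n_phased, 100 * self.ser, 100 * self.wgr, 100 * self.hr


def compare_phasings(
    predicted: np.ndarray,
    truth: np.ndarray,
    phased_mask: np.ndarray,
    k: int,
) -> PhasingComparison:
    """Evaluate a (k, m) prediction against truth on its phased sites only."""
    phased_mask = np.asarray(phased_mask, dtype=bool)
    pred = np.asarray(predicted)[:, phased_mask]
    true = np.asarray(truth)[:, phased_mask]
    return PhasingComparison(
        n_phased=int(phased_mask.sum()),
        ser=switch_error_rate(pred, true, k),
        wgr=wrong_genotype_rate(pred.sum(axis=0), true.sum(axis=0)),
        hr=hamming_rate(pred, true, k),
    )
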