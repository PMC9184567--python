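"""Convenience wrappers for simulation studies: simulate, phase, evaluate."""

from __future__ import annotations

from typing import Tuple

import numpy as np

from .assignment import phasing_to_matrix
from .metrics import PhasingComparison, compare_phasings
from .pipeline import PhasingRun, run_phasing
from .scoring import DEFAULT_WINDOW
from .simulate import SimulatedCross, SimulationConfig, simulate_cross
from .variants import DEFAULT_CLASSES, classify_variant, select_phasable


def phase_simulated_cross(
    sim: SimulatedCross,
    included_classes=DEFAULT_CLASSES,
    W: int = DEFAULT_WINDOW,
    seed: int = 0,
) -> Tuple[PhasingRun, PhasingComparison, np.ndarray]:
    """Phase a simulated cross and score it against its ground truth.

    Selects phasable variants from the *emitted* parental dosages (the
    phaser's view of the data), runs the pipeline, and evaluates on the
    predicted-phased sites.  Returns (run, comparison, phasable indices).
    """
    k = sim.config.k
    dosage_pairs = list(zip(sim.dosage_sprime, sim.dosage_other))
    phasable = np.array(select_phasable(dosage_pairs, included_classes, k))
    classes = [classify_variant(gp, go, k) for gp, go in dosage_pairs]
    run = run_phasing(
        sim.depth_major[phasable],
        sim.depth_minor[phasable],
        k=k,
        W=W,
        classes=[classes[i] for i in phasable],
        seed=seed,
    )
    predicted = phasing_to_matrix(run.phasing, sim.dosage_sprime[phasable])
    mask = run.phasing.haplotype_of_variant != 0
    truth = sim.truth.hap_sprime[:, phasable]
    comparison = compare_phasings(predicted, truth, mask, k)
    return run, comparison, phasable


def run_accuracy_trial(
    m: int,
    p: int,
    coverage: float = 6.0,
    k: int = 4,
    W: int = DEFAULT_WINDOW,
    seed: int = 0,
) -> PhasingComparison:
    """One simulate-phase-evaluate round under the default study design."""
    config = SimulationConfig(k=k, m=m, p=p, coverage=coverage, seed=seed)
    _, comparison, _ = phase_simulated_cross(simulate_cross(config), W=W, seed=seed)
    return comparison
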