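"""Synthetic auto-polyploid F1 crosses with known haplotype ground truth.

Emulates the study design the method targets: two ploidy-k parents, a panel
of p progeny sequenced at low depth (~6x), and biallelic variants drawn from
the phasable classes.  Each progeny inherits a uniformly random k/2-subset
of each parent's haplotypes (optionally perturbed by recombination), and
per-site read counts are binomial around the inherited allele dosage with
Poisson-distributed coverage.

The simulator and the transmission priors of :mod:`kinphase.inheritance`
are independent implementations of the same Mendelian process and serve as
mutual oracles in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import List, Optional, Tuple

import numpy as np

from .variants import VariantClass

_CLASS_ORDER = [
    VariantClass.SIMPLEX_NULLIPLEX,
    VariantClass.SIMPLEX_SIMPLEX,
    VariantClass.DUPLEX_NULLIPLEX,
    VariantClass.OTHER,
]

#: Emitted parental minority dosages per simulated class; OTHER uses (2, 1),
#: an uninformative combination that the variant filter must reject.
_CLASS_DOSAGES = {
    VariantClass.SIMPLEX_NULLIPLEX: (1, 0),
    VariantClass.SIMPLEX_SIMPLEX: (1, 1),
    VariantClass.DUPLEX_NULLIPLEX: (2, 0),
    VariantClass.OTHER: (2, 1),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of one simulated cross.

    Defaults mirror the targeted experimental setting: tetraploid parents,
    ~100 progeny at ~6x coverage, simplex-nulliplex variants only, no
    recombination and error-free parental genotypes.
    """

    k: int = 4
    m: int = 1000
    p: int = 100
    coverage: float = 6.0
    fraction_simplex_nulliplex: float = 1.0
    fraction_simplex_simplex: float = 0.0
    fraction_duplex_nulliplex: float = 0.0
    recombination_rate: float = 0.0
    parent_error_rate: float = 0.0
    seed: int = 0
    chrom: str = "chr1"
    position_spacing: int = 97

    def __post_init__(self):
        if self.k < 2 or self.k % 2:
            raise ValueError("ploidy must be a positive even integer")
        fr = (
            self.fraction_simplex_nulliplex
            + self.fraction_simplex_simplex
            + self.fraction_duplex_nulliplex
        )
        if fr > 1 + 1e-9 or min(
            self.fraction_simplex_nulliplex,
            self.fraction_simplex_simplex,
            self.fraction_duplex_nulliplex,
        ) < 0:
            raise ValueError("class fractions must be non-negative and sum to <= 1")
        for rate in (self.recombination_rate, self.parent_error_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.coverage <= 0:
            raise ValueError("mean coverage must be positive")

    @property
    def class_probabilities(self) -> List[float]:
        named = [
            self.fraction_simplex_nulliplex,
            self.fraction_simplex_simplex,
            self.fraction_duplex_nulliplex,
        ]
        return named + [max(0.0, 1.0 - sum(named))]


@dataclass
class GroundTruth:
    """Everything the simulator knows that the phaser must recover."""

    hap_sprime: np.ndarray  # (k, m) minority indicator on the phased parent
    hap_other: np.ndarray  # (k, m) minority indicator on the other parent
    classes: List[VariantClass]
    marker_haplotypes: List[Tuple[int, ...]]  # s' haplotypes carrying the marker
    inherited_sprime: Optional[np.ndarray] = None  # (p, k) 0/1 at chromosome start
    inherited_other: Optional[np.ndarray] = None

    def cluster_label(self, i: int) -> int:
        """True cluster of a single-marker variant: its s' haplotype (1-based)."""
        haps = self.marker_haplotypes[i]
        if len(haps) != 1:
            raise ValueError("cluster label defined for single-marker variants only")
        return haps[0] + 1


@dataclass
class SimulatedCross:
    """Output bundle of :func:`simulate_cross`."""

    config: SimulationConfig
    positions: np.ndarray  # 1-based, strictly increasing
    dosage_sprime: np.ndarray  # emitted (possibly error-injected) dosages
    dosage_other: np.ndarray
    depth_major: np.ndarray  # (m, p)
    depth_minor: np.ndarray  # (m, p)
    truth: GroundTruth


def _place_markers(rng, k: int, count: int) -> Tuple[int, ...]:
    return tuple(sorted(rng.choice(k, size=count, replace=False)))


def simulate_parents(config: SimulationConfig, rng=None):
    """Draw variant classes and parental haplotypes/genotypes.

    Returns (dosage_sprime, dosage_other, truth).  For every variant the
    minority copies of s' are placed on uniformly chosen haplotypes; the
    emitted dosages optionally carry genotype errors (dosage +-1) at the
    configured rate while the truth keeps the error-free haplotypes.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    k, m = config.k, config.m
    class_idx = rng.choice(4, size=m, p=config.class_probabilities)
    classes = [_CLASS_ORDER[i] for i in class_idx]
    hap_sprime = np.zeros((k, m), dtype=int)
    hap_other = np.zeros((k, m), dtype=int)
    marker_haplotypes: List[Tuple[int, ...]] = []
    for i, cls in enumerate(classes):
        d_p, d_o = _CLASS_DOSAGES[cls]
        haps_p = _place_markers(rng, k, d_p)
        for h in haps_p:
            hap_sprime[h, i] = 1
        for h in _place_markers(rng, k, d_o):
            hap_other[h, i] = 1
        marker_haplotypes.append(haps_p)
    dosage_sprime = hap_sprime.sum(axis=0)
    dosage_other = hap_other.sum(axis=0)
    if config.parent_error_rate > 0:
        for dos in (dosage_sprime, dosage_other):
            hit = rng.random(m) < config.parent_error_rate
            shift = rng.choice([-1, 1], size=m)
            dos[hit] = np.clip(dos[hit] + shift[hit], 0, k)
    truth = GroundTruth(
        hap_sprime=hap_sprime,
        hap_other=hap_other,
        classes=classes,
        marker_haplotypes=marker_haplotypes,
    )
    return dosage_sprime, dosage_other, truth


def _sample_gametes(rng, k: int, p: int) -> np.ndarray:
    """(p, k) 0/1 indicator of the k/2 haplotypes each progeny inherits."""
    subsets = list(combinations(range(k), k // 2))
    picks = rng.integers(len(subsets), size=p)
    out = np.zeros((p, k), dtype=int)
    for s, pick in enumerate(picks):
        out[s, list(subsets[pick])] = 1
    return out


def _inherited_dosage(
    rng, inherited: np.ndarray, hap: np.ndarray, recombination_rate: float
) -> np.ndarray:
    """(p, m) inherited minority dosages from one parent.

    With recombination, at each variant interval each progeny replaces one
    currently inherited haplotype by a uniformly chosen non-inherited one
    with the configured probability (a crossover changes which parental copy
    is transmitted from that point on).
    """
    p, k = inherited.shape
    m = hap.shape[1]
    if recombination_rate == 0:
        return inherited @ hap
    out = np.empty((p, m), dtype=int)
    state = inherited.copy()
    for i in range(m):
        out[:, i] = state @ hap[:, i]
        if i + 1 < m:
            for s in np.flatnonzero(rng.random(p) < recombination_rate):
                have = np.flatnonzero(state[s])
                lack = np.flatnonzero(state[s] == 0)
                state[s, rng.choice(have)] = 0
                state[s, rng.choice(lack)] = 1
    return out


def simulate_progeny(
    config: SimulationConfig, truth: GroundTruth, rng=None
) -> Tuple[np.ndarray, np.ndarray]:
    """Simulate the progeny panel's read depths; extends ``truth`` in place.

    Per progeny and site, coverage ~ Poisson(c) and the minority read count
    is Binomial(coverage, n/k) where n is the progeny's inherited minority
    dosage.  Returns (depth_major, depth_minor), each (m, p).
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    k, p = config.k, config.p
    inherited_p = _sample_gametes(rng, k, p)
    inherited_o = _sample_gametes(rng, k, p)
    truth.inherited_sprime = inherited_p
    truth.inherited_other = inherited_o
    n = _inherited_dosage(
        rng, inherited_p, truth.hap_sprime, config.recombination_rate
    ) + _inherited_dosage(rng, inherited_o, truth.hap_other, config.recombination_rate)
    coverage = rng.poisson(config.coverage, size=n.shape)
    minor = rng.binomial(coverage, n / k)
    return (coverage - minor).T.copy(), minor.T.copy()


def simulate_cross(config: SimulationConfig) -> SimulatedCross:
    """Full simulation: parents, progeny gametes, and read depths."""
    rng = np.random.default_rng(config.seed)
    dosage_sprime, dosage_other, truth = simulate_parents(config, rng)
    depth_major, depth_minor = simulate_progeny(config, truth, rng)
    positions = (np.arange(config.m) * config.position_spacing + 1).astype(int)
    return SimulatedCross(
        config=config,
        positions=positions,
        dosage_sprime=dosage_sprime,
        dosage_other=dosage_other,
        depth_major=depth_major,
        depth_minor=depth_minor,
        truth=truth,
    )


def emit_fixture(
    sim: SimulatedCross,
    vcf_path: str,
    truth_path: Optional[str] = None,
    parent_name: str = "P1",
    other_name: str = "P2",
    progeny_prefix: str = "F",
) -> List[str]:
    """Write the simulated cross as a multi-sample VCF (+ truth table).

    The minority allele is emitted as ALT; parents carry full unphased
    ploidy-k genotypes, progeny carry missing genotypes with ref/alt allele
    depths (AD).  Returns the sample names in header order.
    """
    import pysam

    config = sim.config
    k, m, p = config.k, config.m, config.p
    progeny = [f"{progeny_prefix}{s + 1:03d}" for s in range(p)]
    samples = [parent_name, other_name] + progeny

    header = pysam.VariantHeader()
    header.add_line("##fileformat=VCFv4.2")
    contig_len = int(sim.positions[-1]) + 1000
    header.add_line(f"##contig=<ID={config.chrom},length={contig_len}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">'
    )
    for s in samples:
        header.add_sample(s)

    with pysam.VariantFile(vcf_path, "w", header=header) as out:
        for i in range(m):
            rec = out.new_record(
                contig=config.chrom,
                start=int(sim.positions[i]) - 1,
                stop=int(sim.positions[i]),
                alleles=("A", "T"),
            )
            rec.qual = 100
            rec.filter.add("PASS")
            for name, dosage in (
                (parent_name, int(sim.dosage_sprime[i])),
                (other_name, int(sim.dosage_other[i])),
            ):
                rec.samples[name]["GT"] = tuple([0] * (k - dosage) + [1] * dosage)
                rec.samples[name].phased = False
            for s, name in enumerate(progeny):
                rec.samples[name]["GT"] = (None,) * k
                rec.samples[name]["AD"] = (
                    int(sim.depth_major[i, s]),
                    int(sim.depth_minor[i, s]),
                )
            out.write(rec)

    if truth_path is not None:
        with open(truth_path, "w") as fh:
            hap_cols = "\t".join(f"H{h + 1}" for h in range(k))
            fh.write(f"#CHROM\tPOS\tCLASS\tG_PARENT\tG_OTHER\t{hap_cols}\n")
            for i in range(m):
                haps = "\t".join(str(int(x)) for x in sim.truth.hap_sprime[:, i])
                fh.write(
                    f"{config.chrom}\t{int(sim.positions[i])}\t"
                    f"{sim.truth.classes[i].value}\t{int(sim.dosage_sprime[i])}\t"
                    f"{int(sim.dosage_other[i])}\t{haps}\n"
                )
    return samples
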