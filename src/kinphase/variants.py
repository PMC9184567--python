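"""Parental genotypes, progeny allele depths and phasable-variant classes.

All dosages count the *minority* allele: the less frequent of a biallelic
site's two alleles among the two parents.  The parent to phase is denoted
``s'`` (``parent_to_phase``) and the other parent ``s''``; a variant enters
the pipeline only if it is heterozygous in ``s'``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence


class VariantClass(enum.Enum):
    """Informative variant classes by parental minority dosage (G_s', G_s'')."""

    SIMPLEX_NULLIPLEX = "simplex-nulliplex"  # (1, 0): one traceable marker copy
    SIMPLEX_SIMPLEX = "simplex-simplex"      # (1, 1)
    DUPLEX_NULLIPLEX = "duplex-nulliplex"    # (2, 0)
    OTHER = "other"

    @classmethod
    def from_label(cls, label: str) -> "VariantClass":
        for member in cls:
            if member.value == label:
                return member
        raise ValueError(f"unknown variant class {label!r}")


#: Classes phased by default; simplex-nulliplex markers carry the strongest
#: Mendelian signal (a single traceable minority copy in the phased parent).
DEFAULT_CLASSES = frozenset({VariantClass.SIMPLEX_NULLIPLEX})


@dataclass(frozen=True)
class PloidyConfig:
    """Ploidy and sample roles for one phasing run.

    Parameters
    ----------
    k:
        Even ploidy of all samples (tetraploid potato: k=4).
    parent_to_phase:
        Sample id of the parent whose haplotypes are reconstructed (s').
    other_parent:
        Sample id of the second parent (s'').
    progeny:
        Ordered ids of the p F1 progeny samples.
    """

    k: int
    parent_to_phase: str
    other_parent: str
    progeny: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.k < 2 or self.k % 2 != 0:
            raise ValueError(f"ploidy must be a positive even integer, got {self.k}")
        if self.parent_to_phase == self.other_parent:
            raise ValueError("the two parents must be distinct samples")
        object.__setattr__(self, "progeny", tuple(self.progeny))
        if not self.progeny:
            raise ValueError("progeny list must be non-empty")
        if {self.parent_to_phase, self.other_parent} & set(self.progeny):
            raise ValueError("progeny must be disjoint from the parents")

    @property
    def n_progeny(self) -> int:
        return len(self.progeny)


def determine_minority_allele(parent_allele_counts: Mapping[str, int]):
    """Orient a biallelic site: return ``(majority, minority)`` allele ids.

    ``parent_allele_counts`` maps each allele to its combined dosage over the
    two parents (2k calls in total).  The majority allele is the more frequent
    one; on a tie the lexicographically smaller allele id is the majority so
    that runs are reproducible.

    Raises
    ------
    ValueError
        If the site is not biallelic (not exactly two alleles observed).
    """
    if len(parent_allele_counts) != 2:
        raise ValueError(
            f"site is not biallelic: {len(parent_allele_counts)} alleles observed"
        )
    (a, ca), (b, cb) = sorted(parent_allele_counts.items())
    if ca >= cb:  # tie: lower-ordered allele wins majority
        return a, b
    return b, a


def classify_variant(g_prime: int, g_doubleprime: int, k: int = 4) -> VariantClass:
    """Classify a variant by the parental minority dosages (G_s', G_s'')."""
    for name, g in (("s'", g_prime), ("s''", g_doubleprime)):
        if not 0 <= g <= k:
            raise ValueError(f"dosage {g} of {name} outside 0..{k}")
    if (g_prime, g_doubleprime) == (1, 0):
        return VariantClass.SIMPLEX_NULLIPLEX
    if (g_prime, g_doubleprime) == (1, 1):
        return VariantClass.SIMPLEX_SIMPLEX
    if (g_prime, g_doubleprime) == (2, 0):
        return VariantClass.DUPLEX_NULLIPLEX
    return VariantClass.OTHER


class NoPhasableVariantsError(RuntimeError):
    """Raised when no variant falls into the requested classes."""


def select_phasable(
    dosage_pairs: Sequence[tuple],
    included_classes=DEFAULT_CLASSES,
    k: int = 4,
):
    """Return indices (0-based, genomic order) of variants in the given classes.

    ``dosage_pairs`` is the per-variant sequence of (G_s', G_s'') minority
    dosages.  The returned list defines the index space of all downstream
    stages (scoring window distances are counted in it, not in base pairs).
    """
    included = frozenset(included_classes)
    if not included:
        raise ValueError("included_classes must be non-empty")
    out = [
        i
        for i, (gp, gd) in enumerate(dosage_pairs)
        if classify_variant(gp, gd, k) in included
    ]
    if not out:
        raise NoPhasableVariantsError("no phasable variants in the requested classes")
    return out
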