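"""VCF input/output.

Reads a multi-sample VCF with two fully genotyped parents and low-depth
progeny allele depths (AD) into the minority-oriented matrices the phaser
works on, and writes the phased parent back out with phased genotypes and a
phase-set (PS) tag.  Coordinates are 1-based VCF positions; the internal
variant index space is the rank among phasable variants.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pysam

from .variants import PloidyConfig, classify_variant, VariantClass


@dataclass(frozen=True)
class VariantSite:
    """A parsed biallelic site heterozygous in the phased parent."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    minority_is_alt: bool
    dosage_sprime: int  # minority dosage of s'
    dosage_other: int
    variant_class: VariantClass


@dataclass
class PhasingInput:
    """Sites plus minority-oriented genotype and depth matrices."""

    sites: List[VariantSite]
    dosage_sprime: np.ndarray  # (m,)
    dosage_other: np.ndarray
    depth_major: np.ndarray  # (m, p)
    depth_minor: np.ndarray
    skipped: Counter = field(default_factory=Counter)

    @property
    def n_sites(self) -> int:
        return len(self.sites)


def _dosage(gt: Tuple, allele_index: int) -> int:
    return sum(1 for a in gt if a == allele_index)


def read_inputs(vcf_path: str, config: PloidyConfig) -> PhasingInput:
    """Parse the VCF into the phaser's matrices.

    Kept sites are biallelic, fully genotyped in both parents at ploidy k,
    and heterozygous in the parent to phase.  The minority allele is the
    rarer allele among the two parents (ties: REF stays majority).  Progeny
    genotypes are ignored; a missing AD field means zero coverage for that
    progeny at that site.
    """
    k = config.k
    sites: List[VariantSite] = []
    d_sprime: List[int] = []
    d_other: List[int] = []
    maj_rows: List[List[int]] = []
    min_rows: List[List[int]] = []
    skipped: Counter = Counter()

    with pysam.VariantFile(vcf_path) as vcf:
        present = set(vcf.header.samples)
        missing = (
            {config.parent_to_phase, config.other_parent} | set(config.progeny)
        ) - present
        if missing:
            raise ValueError(f"samples absent from VCF: {sorted(missing)}")
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                skipped["multiallelic_or_monomorphic"] += 1
                continue
            gts = []
            ok = True
            for parent in (config.parent_to_phase, config.other_parent):
                gt = rec.samples[parent].get("GT")
                if gt is None or len(gt) != k or any(a is None for a in gt):
                    skipped["parent_genotype_missing_or_wrong_ploidy"] += 1
                    ok = False
                    break
                gts.append(gt)
            if not ok:
                continue
            alt_total = _dosage(gts[0], 1) + _dosage(gts[1], 1)
            ref_total = 2 * k - alt_total
            minority_is_alt = alt_total <= ref_total  # tie: REF stays majority
            minority_index = 1 if minority_is_alt else 0
            gp = _dosage(gts[0], minority_index)
            go = _dosage(gts[1], minority_index)
            if not 1 <= gp <= k - 1:
                skipped["parent_to_phase_homozygous"] += 1
                continue
            maj_row: List[int] = []
            min_row: List[int] = []
            for progeny in config.progeny:
                ad = rec.samples[progeny].get("AD")
                if ad is None or len(ad) != 2 or any(x is None for x in ad):
                    maj_row.append(0)
                    min_row.append(0)
                else:
                    ref_d, alt_d = int(ad[0]), int(ad[1])
                    if minority_is_alt:
                        maj_row.append(ref_d)
                        min_row.append(alt_d)
                    else:
                        maj_row.append(alt_d)
                        min_row.append(ref_d)
            sites.append(
                VariantSite(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    minority_is_alt=minority_is_alt,
                    dosage_sprime=gp,
                    dosage_other=go,
                    variant_class=classify_variant(gp, go, k),
                )
            )
            d_sprime.append(gp)
            d_other.append(go)
            maj_rows.append(maj_row)
            min_rows.append(min_row)

    p = config.n_progeny
    return PhasingInput(
        sites=sites,
        dosage_sprime=np.array(d_sprime, dtype=int),
        dosage_other=np.array(d_other, dtype=int),
        depth_major=np.array(maj_rows, dtype=int).reshape(len(sites), p),
        depth_minor=np.array(min_rows, dtype=int).reshape(len(sites), p),
        skipped=skipped,
    )


def _phased_genotype(
    k: int, haplotype: int, dosage: int, minority_is_alt: bool
) -> Tuple[int, ...]:
    """Genotype tuple with the minority allele in the assigned slot.

    One minority copy goes to the assigned haplotype slot; for dosage >= 2
    the remaining copies fill the highest other slots deterministically.
    """
    minority = 1 if minority_is_alt else 0
    majority = 1 - minority
    alleles = [majority] * k
    alleles[haplotype - 1] = minority
    extra = dosage - 1
    for slot in range(k, 0, -1):
        if extra <= 0:
            break
        if slot != haplotype:
            alleles[slot - 1] = minority
            extra -= 1
    return tuple(alleles)


def write_phased_vcf(
    in_path: str,
    out_path: str,
    config: PloidyConfig,
    phased_haplotype: Dict[Tuple[str, int], int],
    dosages: Optional[Dict[Tuple[str, int], int]] = None,
    minority_alt: Optional[Dict[Tuple[str, int], bool]] = None,
) -> int:
    """Copy the input VCF, phasing s' genotypes at the assigned sites.

    ``phased_haplotype`` maps (chrom, pos) to the 1..k haplotype carrying
    the minority allele.  All phased sites of a chromosome share one
    phase-set id (the position of its first phased site); every other field
    passes through unchanged.  Returns the number of phased records.
    """
    k = config.k
    n_phased = 0
    with pysam.VariantFile(in_path) as vcf:
        header = vcf.header.copy()
        if "PS" not in header.formats:
            header.formats.add("PS", 1, "Integer", "Phase set identifier")
        block_start: Dict[str, int] = {}
        for (chrom, pos), hap in phased_haplotype.items():
            block_start[chrom] = min(block_start.get(chrom, pos), pos)
        with pysam.VariantFile(out_path, "w", header=header) as out:
            for rec in vcf:
                key = (rec.chrom, rec.pos)
                rec.translate(header)
                hap = phased_haplotype.get(key)
                if hap is not None:
                    dosage = 1 if dosages is None else dosages[key]
                    is_alt = True if minority_alt is None else minority_alt[key]
                    sample = rec.samples[config.parent_to_phase]
                    sample["GT"] = _phased_genotype(k, hap, dosage, is_alt)
                    sample.phased = True
                    sample["PS"] = block_start[rec.chrom]
                    n_phased += 1
                out.write(rec)
    return n_phased


def read_truth_table(path: str):
    """Read a simulator truth table: (positions, classes, (k, m) hap matrix)."""
    positions: List[int] = []
    classes: List[str] = []
    hap_cols: List[List[int]] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            positions.append(int(parts[1]))
            classes.append(parts[2])
            hap_cols.append([int(x) for x in parts[5:]])
    hap = np.array(hap_cols, dtype=int).T  # (k, m)
    return np.array(positions, dtype=int), classes, hap
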