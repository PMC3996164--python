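"""Sire haplotype/genotype imputation and half-sib phasing.

Once each offspring's chromosome has been partitioned into sire-strand blocks,
the sire's two haplotypes follow by averaging, at every marker, the allele
dosages of the offspring that inherited each strand.  Subtracting the
inherited paternal allele from the offspring genotype then yields its maternal
allele, phasing the whole family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .blocking import M, P, U, BlockMatrix
from .data import MISSING, HalfSibFamily

logger = logging.getLogger("halfsib")

#: Missing allele code in haplotypes.
ALLELE_MISSING: int = 9


@dataclass
class SireHaplotypes:
    """The sire's two imputed haplotypes (alleles {0, 1, ALLELE_MISSING}).

    ``support`` counts, per strand and marker, the offspring contributing to
    the average; ``low_confidence`` marks loci whose strand group contained
    both opposing homozygotes (contradictory support); ``conflicts`` marks
    loci proven sire-heterozygous by opposing homozygotes where both imputed
    alleles nevertheless agreed (set to missing).
    """

    markers: list[str]
    hap_p: np.ndarray
    hap_m: np.ndarray
    support: np.ndarray  # (2, n_markers) int
    low_confidence: np.ndarray = field(default=None)  # bool per marker
    conflicts: np.ndarray = field(default=None)  # bool per marker

    def __post_init__(self) -> None:
        n = len(self.markers)
        for hap in (self.hap_p, self.hap_m):
            if hap.shape != (n,) or not np.isin(hap, (0, 1, ALLELE_MISSING)).all():
                raise ValueError("haplotype alleles must be 0/1/missing over markers")
        if self.low_confidence is None:
            self.low_confidence = np.zeros(n, dtype=bool)
        if self.conflicts is None:
            self.conflicts = np.zeros(n, dtype=bool)

    @property
    def genotype(self) -> np.ndarray:
        """Imputed sire genotype: hap_p + hap_m where both known, else MISSING."""
        known = (self.hap_p != ALLELE_MISSING) & (self.hap_m != ALLELE_MISSING)
        out = np.full(len(self.markers), MISSING, dtype=np.int8)
        out[known] = self.hap_p[known] + self.hap_m[known]
        return out


def _strand_allele(
    g: np.ndarray, mask: np.ndarray, rule: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Impute one strand's allele per marker from the offspring carrying it.

    Returns (alleles, support counts, contradictory-support mask).
    """
    count = mask.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean_geno = (g * mask).sum(axis=0) / np.where(count > 0, count, 1)
    hom0 = ((g == 0) & mask).any(axis=0)
    hom2 = ((g == 2) & mask).any(axis=0)
    contradictory = hom0 & hom2

    allele = np.full(g.shape[1], ALLELE_MISSING, dtype=np.int8)
    if rule == "dosage":
        dose = mean_geno / 2.0
        allele[(count > 0) & (dose < 0.5)] = 0
        allele[(count > 0) & (dose > 0.5)] = 1
    elif rule == "genotype":
        # literal genotype-code averaging: threshold 0.5, means above 1 clip to 1
        allele[(count > 0) & (mean_geno < 0.5)] = 0
        allele[(count > 0) & (mean_geno > 0.5)] = 1
    elif rule == "homozygous":
        hmask = mask & ((g == 0) | (g == 2))
        hcount = hmask.sum(axis=0)
        with np.errstate(invalid="ignore"):
            hdose = (g * hmask).sum(axis=0) / 2.0 / np.where(hcount > 0, hcount, 1)
        allele[(hcount > 0) & (hdose < 0.5)] = 0
        allele[(hcount > 0) & (hdose > 0.5)] = 1
        count = hcount
    else:
        raise ValueError(f"unknown imputation rule {rule!r}")
    return allele, count, contradictory


def impute_sire(
    fam: HalfSibFamily,
    blocks: BlockMatrix,
    rule: str = "dosage",
    sire_het: np.ndarray | None = None,
) -> SireHaplotypes:
    """Impute the sire's haplotypes from offspring genotypes grouped by strand.

    For each marker and strand the allele dosages (genotype / 2) of the
    non-missing offspring assigned to that strand are averaged and rounded to
    the nearest of 0/1; an exact 0.5 mean, or an empty strand group, leaves
    the allele missing.  ``rule`` selects the averaging convention:

    - ``"dosage"`` (default): mean of genotype/2, threshold 0.5;
    - ``"genotype"``: mean of raw genotype codes, threshold 0.5, clipped at 1;
    - ``"homozygous"``: average only offspring homozygous at the marker, whose
      paternal allele is unambiguous.

    If ``sire_het`` (the opposing-homozygote mask) is given, loci proven
    sire-heterozygous where both imputed alleles agree are flagged as
    conflicts and set missing.
    """
    g = fam.genotypes.values.astype(np.int32)
    nonmiss = fam.genotypes.values != MISSING
    if blocks.codes.shape != g.shape:
        raise ValueError("block matrix shape does not match family genotypes")

    alle_p, cnt_p, con_p = _strand_allele(g, (blocks.codes == P) & nonmiss, rule)
    alle_m, cnt_m, con_m = _strand_allele(g, (blocks.codes == M) & nonmiss, rule)
    low_conf = con_p | con_m

    conflicts = np.zeros(g.shape[1], dtype=bool)
    if sire_het is not None:
        both = (alle_p != ALLELE_MISSING) & (alle_m != ALLELE_MISSING)
        conflicts = np.asarray(sire_het, dtype=bool) & both & (alle_p == alle_m)
        if conflicts.any():
            logger.info("%d sire-het loci imputed homozygous; set missing", conflicts.sum())
            alle_p = alle_p.copy()
            alle_m = alle_m.copy()
            alle_p[conflicts] = ALLELE_MISSING
            alle_m[conflicts] = ALLELE_MISSING

    return SireHaplotypes(
        list(fam.genotypes.markers),
        alle_p,
        alle_m,
        np.stack([cnt_p, cnt_m]),
        low_conf,
        conflicts,
    )


def percent_imputed(sire: SireHaplotypes) -> float:
    """Fraction of markers with a non-missing imputed sire genotype, in [0, 1]."""
    return float((sire.genotype != MISSING).mean())


@dataclass
class PhasedFamily:
    """Paternal/maternal allele matrices for the half-sibs ({0, 1, ALLELE_MISSING}).

    ``inconsistencies`` lists (offspring id, marker index) cells where the
    block-implied paternal allele contradicted an observed homozygous
    genotype, or a maternal allele came out impossible — both signatures of
    genotyping error.
    """

    individuals: list[str]
    markers: list[str]
    paternal: np.ndarray
    maternal: np.ndarray
    inconsistencies: list[tuple[str, int]] = field(default_factory=list)


def phase_family(
    fam: HalfSibFamily, blocks: BlockMatrix, sire: SireHaplotypes
) -> PhasedFamily:
    """Phase every half-sib into paternal and maternal haplotypes.

    The paternal allele at heterozygous offspring loci is the sire-haplotype
    allele selected by the offspring's block code (missing where the code is
    unknown or the sire allele is missing).  Homozygous offspring loci phase
    trivially from the observed genotype (paternal = maternal = genotype/2);
    when the block-implied allele contradicts a homozygous genotype the
    observed genotype wins and the cell is recorded as an inconsistency.
    The maternal allele is genotype − paternal where the difference is a
    valid allele, else missing (with an inconsistency record).
    """
    g = fam.genotypes.values
    if blocks.codes.shape != g.shape or len(sire.markers) != g.shape[1]:
        raise ValueError("phase_family inputs have mismatched shapes")

    sire_alleles = np.stack([sire.hap_p, sire.hap_m])  # row P then M
    implied = np.full(g.shape, ALLELE_MISSING, dtype=np.int8)
    known_code = blocks.codes != U
    implied[known_code] = sire_alleles[blocks.codes[known_code], np.nonzero(known_code)[1]]

    paternal = np.full(g.shape, ALLELE_MISSING, dtype=np.int8)
    hom = (g == 0) | (g == 2)
    paternal[hom] = g[hom] // 2
    het = g == 1
    paternal[het] = implied[het]

    conflict_cells = hom & (implied != ALLELE_MISSING) & (implied != paternal)
    inconsistencies = [
        (fam.offspring[i], int(j)) for i, j in np.argwhere(conflict_cells)
    ]

    maternal = np.full(g.shape, ALLELE_MISSING, dtype=np.int8)
    ok = (g != MISSING) & (paternal != ALLELE_MISSING)
    diff = g.astype(np.int16) - paternal
    valid = ok & ((diff == 0) | (diff == 1))
    maternal[valid] = diff[valid].astype(np.int8)
    bad = ok & ~valid
    inconsistencies.extend(
        (fam.offspring[i], int(j)) for i, j in np.argwhere(bad)
    )

    return PhasedFamily(
        list(fam.offspring),
        list(fam.genotypes.markers),
        paternal,
        maternal,
        inconsistencies,
    )
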