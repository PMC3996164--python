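"""Core containers: genotype matrices, marker maps, pedigrees and half-sib families.

Genotypes are biallelic SNPs coded as the count of the (arbitrary) alternate
allele: ``0`` and ``2`` are the two homozygotes, ``1`` is heterozygous and
``9`` (:data:`MISSING`) marks a missing call.  All downstream algorithms are
invariant to which homozygote is called 0 versus 2 within a family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("halfsib")

#: Missing genotype code (also used in text formats).
MISSING: int = 9

_VALID_CODES = frozenset({0, 1, 2, MISSING})


@dataclass
class GenotypeMatrix:
    """Individuals x markers matrix of genotype codes {0, 1, 2, MISSING}."""

    individuals: list[str]
    markers: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.individuals = [str(i) for i in self.individuals]
        self.markers = [str(m) for m in self.markers]
        self.values = np.asarray(self.values, dtype=np.int8)
        if len(self.individuals) < 1 or len(self.markers) < 1:
            raise ValueError("GenotypeMatrix needs at least 1 individual and 1 marker")
        if self.values.shape != (len(self.individuals), len(self.markers)):
            raise ValueError(
                f"genotype matrix shape {self.values.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.markers)} markers"
            )
        bad = ~np.isin(self.values, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype code {self.values[i, j]} for individual "
                f"{self.individuals[i]!r} at marker {self.markers[j]!r}"
            )
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("duplicate individual ids")
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("duplicate marker names")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def subset_individuals(self, ids: Sequence[str]) -> "GenotypeMatrix":
        index = {ind: k for k, ind in enumerate(self.individuals)}
        rows = [index[str(i)] for i in ids]
        return GenotypeMatrix(list(ids), list(self.markers), self.values[rows])

    def subset_markers(self, names: Sequence[str]) -> "GenotypeMatrix":
        index = {m: k for k, m in enumerate(self.markers)}
        cols = [index[str(m)] for m in names]
        return GenotypeMatrix(list(self.individuals), list(names), self.values[:, cols])


@dataclass
class MarkerMap:
    """Per-marker chromosome and genetic (cM) and/or physical (bp) position.

    Stored as a DataFrame with columns ``marker``, ``chrom``, ``cm``, ``bp``
    (either of ``cm``/``bp`` may be all-NaN, not both).  Positions must be
    non-decreasing within a chromosome.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.copy()
        required = {"marker", "chrom"}
        if not required.issubset(t.columns):
            raise ValueError("marker map needs columns 'marker' and 'chrom'")
        for col in ("cm", "bp"):
            if col not in t.columns:
                t[col] = np.nan
        t["marker"] = t["marker"].astype(str)
        t["chrom"] = t["chrom"].astype(str)
        if t["marker"].duplicated().any():
            raise ValueError("duplicate marker in map")
        if t["cm"].isna().all() and t["bp"].isna().all():
            raise ValueError("marker map needs cM or bp positions")
        for chrom, sub in t.groupby("chrom", sort=False):
            for col in ("cm", "bp"):
                pos = sub[col].dropna().to_numpy()
                if len(pos) and np.any(np.diff(pos) < 0):
                    raise ValueError(f"{col} positions decrease on chromosome {chrom}")
        self.table = t.reset_index(drop=True)

    @property
    def markers(self) -> list[str]:
        return self.table["marker"].tolist()

    @property
    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.table["chrom"]:
            seen.setdefault(c, None)
        return list(seen)

    def positions(self, prefer: str = "cm") -> np.ndarray:
        """Marker positions, preferring the requested unit, falling back to the other."""
        primary = self.table[prefer].to_numpy(dtype=float)
        if np.isnan(primary).all():
            other = "bp" if prefer == "cm" else "cm"
            primary = self.table[other].to_numpy(dtype=float)
        return primary

    def chrom_slice(self, chrom: str) -> np.ndarray:
        return np.flatnonzero((self.table["chrom"] == str(chrom)).to_numpy())


UNKNOWN_PARENT = "0"


@dataclass
class PedigreeTable:
    """Rows of (individual, sire, dam); ``"0"``/empty means unknown parent."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.copy()
        if not {"individual", "sire", "dam"}.issubset(t.columns):
            raise ValueError("pedigree needs columns individual, sire, dam")
        for col in ("individual", "sire", "dam"):
            t[col] = t[col].fillna(UNKNOWN_PARENT).astype(str)
            t.loc[t[col] == "", col] = UNKNOWN_PARENT
        if t["individual"].duplicated().any():
            dup = t.loc[t["individual"].duplicated(), "individual"].iloc[0]
            raise ValueError(f"duplicate individual id in pedigree: {dup!r}")
        self.table = t.reset_index(drop=True)
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        parents = {
            row.individual: [p for p in (row.sire, row.dam) if p != UNKNOWN_PARENT]
            for row in self.table.itertuples()
        }
        state: dict[str, int] = {}  # 0 visiting, 1 done

        for start in parents:
            if start in state:
                continue
            stack = [(start, iter(parents.get(start, ())))]
            state[start] = 0
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if state.get(p) == 0:
                        raise ValueError(f"pedigree cycle involving {p!r}")
                    if p not in state:
                        state[p] = 0
                        stack.append((p, iter(parents.get(p, ()))))
                        advanced = True
                        break
                if not advanced:
                    state[node] = 1
                    stack.pop()

    def sire_of(self) -> dict[str, str]:
        return dict(zip(self.table["individual"], self.table["sire"]))


@dataclass
class HalfSibFamily:
    """Offspring of one sire: the family genotypes restricted to that sire's progeny."""

    sire: str
    genotypes: GenotypeMatrix

    @property
    def offspring(self) -> list[str]:
        return self.genotypes.individuals

    @property
    def size(self) -> int:
        return self.genotypes.n_individuals


def group_half_sib_families(
    genotypes: GenotypeMatrix, pedigree: PedigreeTable
) -> list[HalfSibFamily]:
    """Partition genotyped individuals into half-sib families by known sire.

    Individuals with an unknown sire are excluded (logged).  Every genotyped
    individual must appear in the pedigree.  A sire that is itself genotyped
    appears as a family head and, independently, as an offspring in its own
    sire's family.
    """
    sire_of = pedigree.sire_of()
    missing = [i for i in genotypes.individuals if i not in sire_of]
    if missing:
        raise ValueError(
            f"{len(missing)} genotyped individuals absent from pedigree, "
            f"first: {missing[0]!r}"
        )
    by_sire: dict[str, list[str]] = {}
    n_unknown = 0
    for ind in genotypes.individuals:
        sire = sire_of[ind]
        if sire == UNKNOWN_PARENT:
            n_unknown += 1
            continue
        by_sire.setdefault(sire, []).append(ind)
    if n_unknown:
        logger.warning("%d genotyped individuals have unknown sire; excluded", n_unknown)
    return [
        HalfSibFamily(sire, genotypes.subset_individuals(offs))
        for sire, offs in by_sire.items()
    ]
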