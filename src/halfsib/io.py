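"""Readers and writers: genotype matrices (TSV/CSV, PLINK PED/MAP), marker
maps, pedigrees, block matrices, recombination events, haplotypes and VCF.

The native genotype dialect is a delimited matrix with a header row of marker
names and a first column of individual ids, codes in {0,1,2,9}.  PLINK
text PED/MAP pairs are collapsed to alternate-allele counts (alternate =
lexicographically larger allele unless an allele-key mapping is supplied).
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .blocking import BlockMatrix, RecombinationEvent
from .data import MISSING, GenotypeMatrix, HalfSibFamily, MarkerMap, PedigreeTable
from .sire import ALLELE_MISSING, PhasedFamily, SireHaplotypes


class ParseError(ValueError):
    pass


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_genotypes(
    path, format: str = "matrix", allele_key: dict[str, str] | None = None
) -> GenotypeMatrix:
    """Read genotypes from a matrix TSV/CSV or a PLINK PED (+ sibling MAP) file.

    ``format`` is ``"matrix"`` or ``"ped"``.  For PED input the MAP file is
    expected at the same path with a ``.map`` suffix, and ``allele_key``
    optionally maps marker name -> counted (alternate) allele.
    """
    path = Path(path)
    if format == "matrix":
        return _read_matrix(path)
    if format == "ped":
        return _read_ped(path, allele_key)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_matrix(path: Path) -> GenotypeMatrix:
    sep = _sep_for(path)
    try:
        df = pd.read_csv(path, sep=sep, header=0, index_col=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty genotype file") from exc
    if df.shape[0] < 1 or df.shape[1] < 1:
        raise ParseError(f"{path}: no genotype data")
    if df.isna().any().any():
        line = int(np.argwhere(df.isna().to_numpy())[0, 0]) + 2
        raise ParseError(f"{path}: malformed row at line {line}")
    try:
        values = df.to_numpy(dtype=np.int16)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric genotype code ({exc})") from exc
    return GenotypeMatrix(df.index.astype(str).tolist(), df.columns.astype(str).tolist(), values)


def write_genotypes(genotypes: GenotypeMatrix, path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        genotypes.values, index=genotypes.individuals, columns=genotypes.markers
    )
    df.to_csv(path, sep=_sep_for(path), index_label="id")


def _read_ped(path: Path, allele_key: dict[str, str] | None) -> GenotypeMatrix:
    map_path = path.with_suffix(".map")
    marker_map = read_marker_map(map_path)
    markers = marker_map.markers
    individuals: list[str] = []
    pairs: list[list[tuple[str, str]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * len(markers):
                raise ParseError(
                    f"{path}: line {lineno} has {len(fields)} fields, "
                    f"expected {6 + 2 * len(markers)}"
                )
            individuals.append(fields[1])
            pairs.append(list(zip(fields[6::2], fields[7::2])))
    if not individuals:
        raise ParseError(f"{path}: empty PED file")

    values = np.full((len(individuals), len(markers)), MISSING, dtype=np.int8)
    for j, marker in enumerate(markers):
        alleles = sorted(
            {a for row in pairs for a in row[j] if a != "0"}
        )
        if len(alleles) > 2:
            raise ParseError(f"{path}: marker {marker!r} is not biallelic: {alleles}")
        if not alleles:
            continue
        alt = allele_key.get(marker) if allele_key else None
        if alt is None:
            alt = alleles[-1]  # lexicographically larger allele counts
        for i, row in enumerate(pairs):
            a, b = row[j]
            if a == "0" or b == "0":
                continue
            values[i, j] = (a == alt) + (b == alt)
    return GenotypeMatrix(individuals, markers, values)


def read_marker_map(path) -> MarkerMap:
    """Read a PLINK-style MAP (chrom, marker, cM, bp) or a headered TSV/CSV map."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if "marker" in first.lower() and "chrom" in first.lower():
        df = pd.read_csv(path, sep=_sep_for(path))
        return MarkerMap(df)
    df = pd.read_csv(
        path, sep=None, engine="python", header=None,
        names=["chrom", "marker", "cm", "bp"],
    )
    df.loc[df["cm"] == 0, "cm"] = np.nan  # PLINK convention: 0 = unknown cM
    return MarkerMap(df)


def write_marker_map(marker_map: MarkerMap, path) -> None:
    marker_map.table.to_csv(Path(path), sep=_sep_for(Path(path)), index=False)


def read_pedigree(path) -> PedigreeTable:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    cols = {c.lower(): c for c in df.columns}
    rename = {}
    for want in ("individual", "sire", "dam"):
        if want in cols:
            rename[cols[want]] = want
    df = df.rename(columns=rename)
    return PedigreeTable(df)


def write_pedigree(pedigree: PedigreeTable, path) -> None:
    pedigree.table.to_csv(Path(path), sep=_sep_for(Path(path)), index=False)


def write_block_matrix(blocks: BlockMatrix, path) -> None:
    """Block matrix CSV with P/M/U character codes."""
    chars = blocks.to_chars()
    df = pd.DataFrame(chars, index=blocks.individuals, columns=blocks.markers)
    df.to_csv(Path(path), index_label="id")


def read_block_matrix(path) -> BlockMatrix:
    df = pd.read_csv(Path(path), index_col=0, dtype=str)
    return BlockMatrix.from_chars(
        df.index.astype(str).tolist(), df.columns.astype(str).tolist(), df.to_numpy()
    )


def write_events(
    events: list[RecombinationEvent], marker_map: MarkerMap, path
) -> None:
    """Recombination intervals as BED-like TSV: chrom, start, end, offspring, change.

    Start/end are the positions of the flanking informative markers
    (half-open [left, right) interval containing the crossover).
    """
    pos = marker_map.positions()
    chroms = marker_map.table["chrom"].to_numpy()
    rows = [
        {
            "chrom": chroms[ev.left],
            "start": pos[ev.left],
            "end": pos[ev.right],
            "offspring": ev.offspring,
            "change": f"{'PM'[ev.from_strand]}->{'PM'[ev.to_strand]}",
        }
        for ev in events
    ]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "offspring", "change"]).to_csv(
        Path(path), sep="\t", index=False
    )


def write_sire_haplotypes(sire: SireHaplotypes, path) -> None:
    """Two haplotype rows plus the imputed genotype row, '.' for missing."""
    def fmt(vec, miss):
        return ["." if v == miss else str(int(v)) for v in vec]

    df = pd.DataFrame(
        [
            fmt(sire.hap_p, ALLELE_MISSING),
            fmt(sire.hap_m, ALLELE_MISSING),
            fmt(sire.genotype, MISSING),
        ],
        index=["hap_P", "hap_M", "genotype"],
        columns=sire.markers,
    )
    df.to_csv(Path(path), sep="\t", index_label="row")


def write_phased_output(
    family: HalfSibFamily,
    phased: PhasedFamily,
    path,
    format: str = "haplotypes",
    marker_map: MarkerMap | None = None,
) -> None:
    """Write phased offspring as a haplotype TSV or a phased-GT VCF.

    The haplotype TSV has two rows per individual (``<id>_pat``,
    ``<id>_mat``) with alleles {0, 1, "."}.  The VCF writes ``paternal|maternal``
    phased genotypes with '.' for unphased alleles and requires a marker map.
    """
    if format == "haplotypes":
        _write_hap_tsv(phased, path)
    elif format == "vcf":
        if marker_map is None:
            raise ValueError("VCF output requires a marker map")
        _write_vcf(phased, marker_map, path)
    else:
        raise ValueError(f"unknown phased output format {format!r}")


def _write_hap_tsv(phased: PhasedFamily, path) -> None:
    rows = {}
    for i, ind in enumerate(phased.individuals):
        rows[f"{ind}_pat"] = [
            "." if v == ALLELE_MISSING else str(int(v)) for v in phased.paternal[i]
        ]
        rows[f"{ind}_mat"] = [
            "." if v == ALLELE_MISSING else str(int(v)) for v in phased.maternal[i]
        ]
    pd.DataFrame.from_dict(rows, orient="index", columns=phased.markers).to_csv(
        Path(path), sep="\t", index_label="haplotype"
    )


def read_phased_haplotypes(path) -> tuple[list[str], list[str], np.ndarray, np.ndarray]:
    """Read a haplotype TSV back: (individuals, markers, paternal, maternal)."""
    df = pd.read_csv(Path(path), sep="\t", index_col=0, dtype=str)
    pat_rows = [r for r in df.index if r.endswith("_pat")]
    individuals = [r[: -len("_pat")] for r in pat_rows]

    def decode(rows):
        arr = df.loc[rows].to_numpy()
        out = np.full(arr.shape, ALLELE_MISSING, dtype=np.int8)
        out[arr == "0"] = 0
        out[arr == "1"] = 1
        return out

    paternal = decode(pat_rows)
    maternal = decode([f"{ind}_mat" for ind in individuals])
    return individuals, df.columns.astype(str).tolist(), paternal, maternal


def _write_vcf(phased: PhasedFamily, marker_map: MarkerMap, path) -> None:
    header = pysam.VariantHeader()
    for chrom in marker_map.chromosomes:
        header.contigs.add(chrom)
    header.formats.add("GT", 1, "String", "Phased genotype (paternal|maternal)")
    for ind in phased.individuals:
        header.add_sample(ind)

    table = marker_map.table
    bp = table["bp"].to_numpy(dtype=float)
    if np.isnan(bp).all():
        # no physical positions: use the cM position scaled to an integer grid
        bp = np.round(table["cm"].to_numpy(dtype=float) * 1e4) + 1

    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for j, marker in enumerate(phased.markers):
            rec = vcf.new_record(
                contig=str(table["chrom"].iloc[j]),
                start=int(bp[j]) - 1,
                stop=int(bp[j]),
                alleles=("A", "B"),
                id=marker,
            )
            for i, ind in enumerate(phased.individuals):
                p = phased.paternal[i, j]
                m = phased.maternal[i, j]
                rec.samples[ind]["GT"] = (
                    None if p == ALLELE_MISSING else int(p),
                    None if m == ALLELE_MISSING else int(m),
                )
                rec.samples[ind].phased = True
            vcf.write(rec)
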