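"""Containers, family grouping, and file format round-trips."""

import numpy as np
import pandas as pd
import pytest

from halfsib import (
    MISSING,
    GenotypeMatrix,
    MarkerMap,
    PedigreeTable,
    group_half_sib_families,
)
from halfsib import io as hio
from halfsib.sire import ALLELE_MISSING, PhasedFamily

from conftest import make_family


def test_genotype_matrix_validation():
    with pytest.raises(ValueError):
        GenotypeMatrix(["a"], ["m"], np.array([[3]]))
    with pytest.raises(ValueError):
        GenotypeMatrix(["a", "a"], ["m"], np.array([[0], [1]]))
    with pytest.raises(ValueError):
        GenotypeMatrix([], [], np.empty((0, 0)))
    gm = GenotypeMatrix(["a", "b"], ["m1", "m2"], np.array([[0, 9], [2, 1]]))
    assert gm.subset_individuals(["b"]).values.tolist() == [[2, 1]]
    assert gm.subset_markers(["m2"]).values.tolist() == [[9], [1]]


def test_marker_map_requires_sorted_positions():
    with pytest.raises(ValueError):
        MarkerMap(pd.DataFrame({"marker": ["a", "b"], "chrom": "1", "cm": [2.0, 1.0]}))
    mm = MarkerMap(
        pd.DataFrame(
            {"marker": ["a", "b", "c"], "chrom": ["1", "1", "2"], "cm": [1.0, 2.0, 0.5]}
        )
    )
    assert mm.chromosomes == ["1", "2"]
    assert mm.chrom_slice("1").tolist() == [0, 1]


def test_pedigree_rejects_cycles_and_duplicates():
    with pytest.raises(ValueError):
        PedigreeTable(
            pd.DataFrame(
                {"individual": ["a", "b"], "sire": ["b", "a"], "dam": ["0", "0"]}
            )
        )
    with pytest.raises(ValueError):
        PedigreeTable(
            pd.DataFrame(
                {"individual": ["a", "a"], "sire": ["0", "0"], "dam": ["0", "0"]}
            )
        )


def test_group_half_sib_families_partitions_known_sire_offspring():
    g = GenotypeMatrix(
        [f"o{i}" for i in range(6)], ["m1"], np.zeros((6, 1), dtype=np.int8)
    )
    ped = PedigreeTable(
        pd.DataFrame(
            {
                "individual": [f"o{i}" for i in range(6)],
                "sire": ["s1", "s1", "s1", "s2", "s2", "s2"],
                "dam": "0",
            }
        )
    )
    fams = group_half_sib_families(g, ped)
    assert sorted((f.sire, f.size) for f in fams) == [("s1", 3), ("s2", 3)]
    seen = [o for f in fams for o in f.offspring]
    assert sorted(seen) == sorted(g.individuals)


def test_group_unknown_sires_excluded():
    g = GenotypeMatrix(["o1"], ["m1"], np.zeros((1, 1), dtype=np.int8))
    ped = PedigreeTable(pd.DataFrame({"individual": ["o1"], "sire": ["0"], "dam": ["0"]}))
    assert group_half_sib_families(g, ped) == []


def test_group_sire_can_also_be_offspring():
    g = GenotypeMatrix(
        ["s2", "o1"], ["m1"], np.zeros((2, 1), dtype=np.int8)
    )
    ped = PedigreeTable(
        pd.DataFrame(
            {"individual": ["s2", "o1"], "sire": ["s1", "s2"], "dam": ["0", "0"]}
        )
    )
    fams = {f.sire: f.offspring for f in group_half_sib_families(g, ped)}
    assert fams == {"s1": ["s2"], "s2": ["o1"]}


def test_matrix_read_write_round_trip(tmp_path):
    gm = GenotypeMatrix(
        ["a", "b", "c"],
        [f"m{j}" for j in range(8)],
        np.array(
            [
                [0, 1, 2, 9, 0, 2, 1, 0],
                [2, 1, 0, 0, 2, 2, 1, 1],
                [1, 1, 1, 2, 0, 9, 0, 2],
            ]
        ),
    )
    for ext in ("tsv", "csv"):
        path = tmp_path / f"geno.{ext}"
        hio.write_genotypes(gm, path)
        back = hio.read_genotypes(path)
        assert back.individuals == gm.individuals
        assert back.markers == gm.markers
        assert (back.values == gm.values).all()


def test_empty_genotype_file_errors(tmp_path):
    path = tmp_path / "empty.tsv"
    path.write_text("")
    with pytest.raises(hio.ParseError):
        hio.read_genotypes(path)


def test_malformed_matrix_row_names_line(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("id\tm1\tm2\na\t0\t1\nb\t2\n")
    with pytest.raises(hio.ParseError, match="line"):
        hio.read_genotypes(path)


def test_ped_allele_collapse(tmp_path):
    (tmp_path / "fam.map").write_text("1\tm1\t0\t100\n1\tm2\t0\t200\n")
    (tmp_path / "fam.ped").write_text("F A 0 0 1 0 A A A B\n")
    gm = hio.read_genotypes(tmp_path / "fam.ped", format="ped")
    # m1 has only allele A (counted); m2 counts the lexicographically larger B
    assert gm.values.tolist() == [[2, 1]]
    assert gm.individuals == ["A"]


def test_ped_missing_and_non_biallelic(tmp_path):
    (tmp_path / "f.map").write_text("1\tm1\t0\t100\n")
    (tmp_path / "f.ped").write_text("F A 0 0 1 0 0 0\nF B 0 0 1 0 A C\nF C 0 0 1 0 A G\n")
    with pytest.raises(hio.ParseError, match="m1"):
        hio.read_genotypes(tmp_path / "f.ped", format="ped")
    (tmp_path / "g.map").write_text("1\tm1\t0\t100\n")
    (tmp_path / "g.ped").write_text("F A 0 0 1 0 0 0\nF B 0 0 1 0 A C\n")
    gm = hio.read_genotypes(tmp_path / "g.ped", format="ped")
    assert gm.values.tolist() == [[MISSING], [1]]


def _phased_fixture():
    pat = np.array([[0, 1, ALLELE_MISSING], [1, 0, 1]], dtype=np.int8)
    mat = np.array([[1, 0, ALLELE_MISSING], [0, 0, 1]], dtype=np.int8)
    fam = make_family([[1, 1, 9], [1, 0, 2]])
    return fam, PhasedFamily(fam.offspring, fam.genotypes.markers, pat, mat)


def test_phased_haplotype_tsv_round_trip_and_determinism(tmp_path):
    fam, phased = _phased_fixture()
    p1 = tmp_path / "phased.tsv"
    hio.write_phased_output(fam, phased, p1)
    inds, markers, pat, mat = hio.read_phased_haplotypes(p1)
    assert inds == fam.offspring and markers == fam.genotypes.markers
    assert (pat == phased.paternal).all() and (mat == phased.maternal).all()
    p2 = tmp_path / "phased2.tsv"
    hio.write_phased_output(
        fam, PhasedFamily(inds, markers, pat, mat), p2
    )
    assert p1.read_bytes() == p2.read_bytes()


def test_phased_vcf_output(tmp_path):
    import pysam

    fam, phased = _phased_fixture()
    mm = MarkerMap(
        pd.DataFrame(
            {"marker": fam.genotypes.markers, "chrom": "1", "bp": [100, 200, 300]}
        )
    )
    path = tmp_path / "phased.vcf"
    hio.write_phased_output(fam, phased, path, format="vcf", marker_map=mm)
    with pysam.VariantFile(str(path)) as vcf:
        records = list(vcf)
    assert [r.pos for r in records] == [100, 200, 300]
    gt0 = records[0].samples[fam.offspring[0]]
    assert gt0["GT"] == (0, 1) and gt0.phased
    # unphased locus carries missing alleles
    gt_missing = records[2].samples[fam.offspring[0]]
    assert gt_missing["GT"] == (None, None)


def test_block_matrix_csv_round_trip(tmp_path):
    from halfsib import BlockMatrix, U

    bm = BlockMatrix(["a", "b"], ["m1", "m2", "m3"], np.array([[0, 1, U], [U, 0, 0]]))
    path = tmp_path / "blocks.csv"
    hio.write_block_matrix(bm, path)
    back = hio.read_block_matrix(path)
    assert (back.codes == bm.codes).all()
    assert back.individuals == bm.individuals


def test_events_bed_output(tmp_path):
    from halfsib import RecombinationEvent

    mm = MarkerMap(
        pd.DataFrame({"marker": ["m1", "m2", "m3"], "chrom": "1", "cm": [0.5, 1.0, 2.0]})
    )
    events = [RecombinationEvent("o1", 0, 2, 0, 1)]
    path = tmp_path / "events.tsv"
    hio.write_events(events, mm, path)
    df = pd.read_csv(path, sep="\t")
    assert df.loc[0, ["chrom", "start", "end", "offspring", "change"]].tolist() == [
        1, 0.5, 2.0, "o1", "P->M",
    ]


@pytest.mark.parametrize("seed", range(8))
def test_random_matrix_round_trip(seed, tmp_path):
    rng = np.random.default_rng(seed)
    n, m = int(rng.integers(1, 6)), int(rng.integers(1, 10))
    values = rng.choice([0, 1, 2, 9], size=(n, m))
    gm = GenotypeMatrix(
        [f"i{k}" for k in range(n)], [f"m{k}" for k in range(m)], values
    )
    path = tmp_path / "g.csv"
    hio.write_genotypes(gm, path)
    assert (hio.read_genotypes(path).values == gm.values).all()
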