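"""Shared fixtures: small hand-built families and session-scoped simulation
benchmarks reused across the evaluation tests."""

import numpy as np
import pytest

from halfsib import GenotypeMatrix, HalfSibFamily, SimConfig, simulate_population
from halfsib.pipeline import run_benchmark


def make_family(rows, sire="S", markers=None):
    """HalfSibFamily from a list of genotype rows."""
    rows = np.asarray(rows, dtype=np.int8)
    inds = [f"O{i + 1}" for i in range(rows.shape[0])]
    markers = markers or [f"M{j + 1}" for j in range(rows.shape[1])]
    return HalfSibFamily(sire, GenotypeMatrix(inds, markers, rows))


def family_from_parts(sire, strands, mat, error_cells=(), rng=None):
    """Assemble a family's genotypes from sire haplotypes, per-offspring
    paternal strand-of-origin rows and maternal allele rows."""
    n_markers = sire.shape[1]
    pat = sire[strands, np.arange(n_markers)]
    geno = (pat + mat).astype(np.int8)
    for i, j in error_cells:
        geno[i, j] = (geno[i, j] + 1 + rng.integers(0, 2)) % 3
    return make_family(geno)


def synthetic_family(
    rng, n_offspring, n_markers, crossovers=(), error_cells=(), freq=0.5
):
    """Family built directly from a random sire and unrelated dams.

    ``crossovers`` is a list of (offspring index, marker index) where the
    paternal gamete switches sire strand; ``error_cells`` of (offspring,
    marker) cells are flipped to a different genotype code.  Returns
    (family, true paternal strand matrix {0,1}).
    """
    sire = rng.integers(0, 2, size=(2, n_markers)).astype(np.int8)
    strands = np.zeros((n_offspring, n_markers), dtype=np.int8)
    for i in range(n_offspring):
        strands[i] = i % 2
    for i, j in crossovers:
        strands[i, j:] = 1 - strands[i, j:]
    mat = (rng.uniform(size=(n_offspring, n_markers)) < freq).astype(np.int8)
    fam = family_from_parts(sire, strands, mat, error_cells, rng)
    return fam, strands


def oracle_min_total_switches(genotypes):
    """Exhaustive minimum of total strand switches consistent with the data.

    Considers every assignment of a strand orientation to every
    opposing-homozygote locus (equivalently every strand labelling consistent
    with the homozygous constraints) by exact dynamic programming over the
    per-offspring strand state — feasible for small families where brute
    enumeration over orientations would already be exponential.
    """
    g = np.asarray(genotypes)
    n = g.shape[0]
    cols = np.flatnonzero((g == 0).any(0) & (g == 2).any(0))
    states = {(None,) * n: 0}
    for j in cols:
        col = g[:, j]
        hom = np.flatnonzero((col == 0) | (col == 2))
        if len(hom) == 0:
            continue
        new_states = {}
        for state, cost in states.items():
            for orient in (0, 1):
                s = list(state)
                c = cost
                for i in hom:
                    strand = orient if col[i] == 0 else 1 - orient
                    if s[i] is not None and s[i] != strand:
                        c += 1
                    s[i] = strand
                key = tuple(s)
                if key not in new_states or c < new_states[key]:
                    new_states[key] = c
        states = new_states
    return min(states.values()) if states else 0


@pytest.fixture(scope="session")
def bench_clean():
    """Dataset-B-style population, 10 000 markers, no errors, 20 families."""
    return run_benchmark(
        n_markers=10_000, error_rate=0.0, sizes=(4, 8, 10, 40), n_families=20, seed=1
    )


@pytest.fixture(scope="session")
def bench_errors():
    """Same design with 1% genotyping errors."""
    return run_benchmark(
        n_markers=10_000, error_rate=0.01, sizes=(4, 10, 40), n_families=20, seed=1
    )


@pytest.fixture(scope="session")
def bench_low_density_errors():
    """1250 markers (2.5 per cM), 1% errors, families of 4."""
    return run_benchmark(
        n_markers=1250, error_rate=0.01, sizes=(4,), n_families=20, seed=1
    )


@pytest.fixture(scope="session")
def dataset_c():
    """Dataset-C-style population: 10 sires x 200 dams, 10 generations."""
    cfg = SimConfig(
        n_markers=10_000,
        n_sires=10,
        n_dams=200,
        offspring_per_sire=40,
        n_generations=10,
        founder_freq=0.5,
        seed=2,
    )
    return simulate_population(cfg)
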