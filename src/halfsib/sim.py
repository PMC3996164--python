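"""Truth-tracked forward-in-time simulator of half-sib livestock populations.

Emulates a commercial-livestock design: founder haplotypes drawn at
per-marker allele frequencies ~ U(0,1), several generations of random mating
between a small number of sires and a large number of dams on a single
chromosome, then a recorded generation of paternal half-sib families.  Every
meiosis draws a crossover count (Poisson with mean = map length in Morgans,
i.e. Haldane's no-interference model, or a uniform count), places crossovers
uniformly on the genetic map, and copies alternating parental strands.  The
simulator records, for each recorded offspring, both haplotypes with parental
labels, the paternal gamete's true strand-of-origin per marker, and crossover
positions — the ground truth for all evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .blocking import BlockMatrix
from .data import MISSING, GenotypeMatrix, HalfSibFamily, MarkerMap, PedigreeTable

POISSON = "poisson-haldane"
UNIFORM = "uniform-count"


@dataclass
class SimConfig:
    """Simulation design parameters.

    Defaults emulate a 500 cM chromosome genotyped at 20 markers per cM, with
    20 sires each mated to 20 dams per generation producing 40 recorded
    half-sibs per sire, preceded by extra random-mating burn-in generations
    that stand in for the historical population of a livestock breed.
    """

    n_markers: int = 10_000
    map_length_cm: float = 500.0
    n_generations: int = 16
    n_sires: int = 20
    n_dams: int = 400
    offspring_per_sire: int = 40
    crossover_model: str = POISSON
    uniform_max_crossovers: int = 6
    founder_freq: str | float = "uniform"
    error_rate: float = 0.0
    burn_in: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_markers", "n_generations", "n_sires", "n_dams", "offspring_per_sire"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if self.crossover_model not in (POISSON, UNIFORM):
            raise ValueError(f"unknown crossover model {self.crossover_model!r}")
        if isinstance(self.founder_freq, str):
            if self.founder_freq != "uniform":
                raise ValueError("founder_freq must be 'uniform' or a frequency in (0, 1)")
        elif not 0 < self.founder_freq < 1:
            raise ValueError("founder_freq must be 'uniform' or a frequency in (0, 1)")
        if self.n_dams < self.n_sires:
            raise ValueError("need at least one dam per sire")


@dataclass
class TruthSet:
    """Ground truth for a simulated population.

    ``haplotypes`` maps individual id -> (paternal, maternal) allele vectors;
    ``crossovers`` maps offspring id -> paternal-meiosis crossover positions
    (cM); ``blocks`` maps sire id -> true strand-of-origin BlockMatrix of its
    recorded family (0 = sire's first strand); ``sire_genotypes`` maps sire id
    -> true genotype vector.
    """

    haplotypes: dict[str, tuple[np.ndarray, np.ndarray]]
    crossovers: dict[str, np.ndarray]
    blocks: dict[str, BlockMatrix]
    sire_genotypes: dict[str, np.ndarray]


@dataclass
class SimResult:
    genotypes: GenotypeMatrix
    pedigree: PedigreeTable
    marker_map: MarkerMap
    truth: TruthSet
    families: list[HalfSibFamily]
    error_cells: list[tuple[str, int]] = field(default_factory=list)


def marker_positions(cfg: SimConfig) -> np.ndarray:
    """Evenly spaced genetic positions (cM), strictly inside (0, L)."""
    return (np.arange(cfg.n_markers) + 0.5) * cfg.map_length_cm / cfg.n_markers


def simulate_founders(
    cfg: SimConfig,
    rng: np.random.Generator,
    n_haplotypes: int,
    freqs: np.ndarray | None = None,
) -> np.ndarray:
    """Founder haplotype pool: allele 1 at marker j with frequency p_j ~ U(0,1).

    The frequencies are shared across every founder haplotype; pass ``freqs``
    to draw several pools from the same marker frequencies.
    """
    if freqs is None:
        freqs = rng.uniform(0.0, 1.0, cfg.n_markers)
    return (rng.uniform(size=(n_haplotypes, cfg.n_markers)) < freqs).astype(np.int8)


def make_gamete(
    parent: np.ndarray, cfg: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One meiosis: returns (gamete haplotype, crossover positions cM, per-marker strand).

    The crossover count follows the configured model; positions are i.i.d.
    uniform on (0, L); the gamete copies alternating parental strands starting
    from a fair-coin strand.  ``strand[j]`` is 0/1 = which parental strand
    marker j came from.
    """
    L = cfg.map_length_cm
    if cfg.crossover_model == POISSON:
        k = int(rng.poisson(L / 100.0))
    else:
        k = int(rng.integers(0, cfg.uniform_max_crossovers + 1))
    xos = np.sort(rng.uniform(0.0, L, k))
    start = int(rng.integers(2))
    pos = marker_positions(cfg)
    strand = ((np.searchsorted(xos, pos, side="right") + start) % 2).astype(np.int8)
    gamete = np.where(strand == 0, parent[0], parent[1])
    return gamete, xos, strand


def _mate(
    sire: np.ndarray, dam: np.ndarray, cfg: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    pat, xos, strand = make_gamete(sire, cfg, rng)
    mat, _, _ = make_gamete(dam, cfg, rng)
    return pat, mat, xos, strand


def simulate_population(cfg: SimConfig, rng: np.random.Generator | None = None) -> SimResult:
    """Run the full forward simulation and return genotypes plus truth.

    Burn-in and pedigree generations proceed by random mating (each new
    individual draws a random sire and dam from the previous generation);
    the final recorded generation forms ``n_sires`` half-sib families of
    ``offspring_per_sire``, with each sire's dams drawn without replacement
    from its share of the dam pool (round-robin litters when families are
    larger than the pool).  Deterministic under a seeded generator.
    """
    if cfg.offspring_per_sire > 0 and cfg.n_dams // cfg.n_sires < 1:
        raise ValueError("infeasible config: no dams available per sire")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    if cfg.founder_freq == "uniform":
        freqs = rng.uniform(0.0, 1.0, cfg.n_markers)
    else:
        # fixed founder frequency (0.5 emulates the historical-population
        # convention of livestock simulators: all markers start segregating
        # at intermediate frequency)
        freqs = np.full(cfg.n_markers, float(cfg.founder_freq))
    n_pop = cfg.n_sires + cfg.n_dams

    # historical burn-in: random mating in an unstructured population of the
    # same census size (any individual may parent), building up LD without the
    # strong sire bottleneck of the recent structured generations
    pop = simulate_founders(cfg, rng, 2 * n_pop, freqs).reshape(n_pop, 2, -1)
    for _ in range(cfg.burn_in):
        pa = rng.integers(0, n_pop, n_pop)
        ma = rng.integers(0, n_pop, n_pop)
        children = np.empty_like(pop)
        for c in range(n_pop):
            pat, mat, _, _ = _mate(pop[pa[c]], pop[ma[c]], cfg, rng)
            children[c, 0] = pat
            children[c, 1] = mat
        pop = children
    males = pop[: cfg.n_sires]
    females = pop[cfg.n_sires :]

    # recent structured generations: few sires, many dams
    n_pedigree_gens = max(cfg.n_generations - 1, 0)
    for _ in range(n_pedigree_gens):
        sire_idx = rng.integers(0, cfg.n_sires, n_pop)
        dam_idx = rng.integers(0, cfg.n_dams, n_pop)
        children = np.empty((n_pop, 2, cfg.n_markers), dtype=np.int8)
        for c in range(n_pop):
            pat, mat, _, _ = _mate(males[sire_idx[c]], females[dam_idx[c]], cfg, rng)
            children[c, 0] = pat
            children[c, 1] = mat
        males = children[: cfg.n_sires]
        females = children[cfg.n_sires :]

    # recorded half-sib generation
    dams_per_sire = cfg.n_dams // cfg.n_sires
    individuals: list[str] = []
    ped_rows: list[tuple[str, str, str]] = []
    geno_rows: list[np.ndarray] = []
    haplotypes: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    crossovers: dict[str, np.ndarray] = {}
    blocks: dict[str, BlockMatrix] = {}
    sire_genotypes: dict[str, np.ndarray] = {}
    family_members: dict[str, list[str]] = {}

    marker_names = [f"M{j + 1}" for j in range(cfg.n_markers)]
    for s in range(cfg.n_sires):
        sire_id = f"S{s + 1}"
        sire_genotypes[sire_id] = (males[s, 0] + males[s, 1]).astype(np.int8)
        haplotypes[sire_id] = (males[s, 0].copy(), males[s, 1].copy())
        ped_rows.append((sire_id, "0", "0"))
        dam_pool = np.arange(s * dams_per_sire, (s + 1) * dams_per_sire)
        strand_rows = []
        members = []
        for o in range(cfg.offspring_per_sire):
            child_id = f"S{s + 1}O{o + 1}"
            dam = int(dam_pool[o % dams_per_sire])
            dam_id = f"D{dam + 1}"
            pat, mat, xos, strand = _mate(males[s], females[dam], cfg, rng)
            individuals.append(child_id)
            members.append(child_id)
            ped_rows.append((child_id, sire_id, dam_id))
            geno_rows.append((pat + mat).astype(np.int8))
            haplotypes[child_id] = (pat, mat)
            crossovers[child_id] = xos
            strand_rows.append(strand)
        blocks[sire_id] = BlockMatrix(members, marker_names, np.vstack(strand_rows))
        family_members[sire_id] = members

    genotypes = GenotypeMatrix(individuals, marker_names, np.vstack(geno_rows))
    error_cells: list[tuple[str, int]] = []
    if cfg.error_rate > 0:
        genotypes, error_cells = inject_errors(genotypes, cfg.error_rate, rng)

    pedigree = PedigreeTable(
        pd.DataFrame(ped_rows, columns=["individual", "sire", "dam"])
    )
    marker_map = MarkerMap(
        pd.DataFrame(
            {"marker": marker_names, "chrom": "1", "cm": marker_positions(cfg)}
        )
    )
    families = [
        HalfSibFamily(sire_id, genotypes.subset_individuals(members))
        for sire_id, members in family_members.items()
    ]
    truth = TruthSet(haplotypes, crossovers, blocks, sire_genotypes)
    return SimResult(genotypes, pedigree, marker_map, truth, families, error_cells)


def inject_errors(
    genotypes: GenotypeMatrix, rate: float, rng: np.random.Generator
) -> tuple[GenotypeMatrix, list[tuple[str, int]]]:
    """Rewrite floor(rate x non-missing cells) distinct cells to a different code.

    Each selected cell gets a uniformly random code among the two codes in
    {0, 1, 2} differing from its current value.  Returns the perturbed matrix
    and the list of (individual id, marker index) error cells.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    values = genotypes.values.copy()
    flat_nonmiss = np.flatnonzero(values.ravel() != MISSING)
    n_err = int(rate * len(flat_nonmiss))
    if n_err == 0:
        return genotypes, []
    chosen = rng.choice(flat_nonmiss, size=n_err, replace=False)
    old = values.ravel()[chosen]
    shift = rng.integers(1, 3, n_err).astype(np.int8)
    values.ravel()[chosen] = (old + shift) % 3
    n_markers = genotypes.n_markers
    cells = [
        (genotypes.individuals[int(c) // n_markers], int(c) % n_markers)
        for c in chosen
    ]
    return (
        GenotypeMatrix(list(genotypes.individuals), list(genotypes.markers), values),
        cells,
    )


def subsample_family(
    fam: HalfSibFamily, truth_blocks: BlockMatrix, size: int, start: int = 0
) -> tuple[HalfSibFamily, BlockMatrix]:
    """A sub-family of ``size`` consecutive offspring (for family-size sweeps)."""
    ids = fam.offspring[start : start + size]
    if len(ids) < size:
        raise ValueError("not enough offspring to subsample")
    rows = list(range(start, start + size))
    sub_blocks = BlockMatrix(ids, list(truth_blocks.markers), truth_blocks.codes[rows])
    return HalfSibFamily(fam.sire, fam.genotypes.subset_individuals(ids)), sub_blocks
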