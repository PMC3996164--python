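"""End-to-end pipeline and simulation benchmarks.

:func:`phase_pipeline` chains blocking, uncertainty filling, sire imputation
and offspring phasing for one half-sib family.  The benchmark helpers run the
pipeline over simulated populations at several family sizes and collect the
accuracy statistics (block R², sire-imputation R² and % imputed, phasing R²,
switch error rate, % het sites phased/correct) used to characterise the
method.  Family-size sweeps subsample disjoint subsets of each simulated
family, so one simulated population serves every size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .blocking import BlockResult, block_partition, fill_uncertain_codes
from .data import HalfSibFamily
from .metrics import (
    EvaluationReport,
    block_r2,
    het_correct_fraction,
    het_phased_fraction,
    r2_genotypes,
    r2_haplotypes,
    switch_error_rate,
)
from .sim import SimConfig, SimResult, simulate_population, subsample_family
from .sire import PhasedFamily, SireHaplotypes, impute_sire, percent_imputed, phase_family


@dataclass
class FamilyPipelineResult:
    family: HalfSibFamily
    block_result: BlockResult
    sire: SireHaplotypes
    phased: PhasedFamily


def phase_pipeline(
    fam: HalfSibFamily,
    window: int = 30,
    confirm: int = 3,
    rule: str = "dosage",
) -> FamilyPipelineResult:
    """Block, impute and phase one half-sib family."""
    res = block_partition(fam, window=window, confirm=confirm)
    filled = fill_uncertain_codes(res.blocks)
    sire = impute_sire(fam, filled, rule=rule, sire_het=res.sire_het)
    phased = phase_family(fam, filled, sire)
    return FamilyPipelineResult(fam, res, sire, phased)


def evaluate_family(
    result: FamilyPipelineResult, sim: SimResult
) -> dict[str, float]:
    """Accuracy statistics of one pipeline run against the simulation truth."""
    fam = result.family
    truth_blocks = sim.truth.blocks[fam.sire]
    # align truth rows to (possibly subsampled) family members
    idx = {ind: k for k, ind in enumerate(truth_blocks.individuals)}
    rows = [idx[ind] for ind in fam.offspring]
    truth_codes = truth_blocks.codes[rows]
    from .blocking import BlockMatrix

    tb = BlockMatrix(list(fam.offspring), list(truth_blocks.markers), truth_codes)

    truth_pat = np.vstack([sim.truth.haplotypes[ind][0] for ind in fam.offspring])
    truth_mat = np.vstack([sim.truth.haplotypes[ind][1] for ind in fam.offspring])

    phased = result.phased
    per_ind = {
        "phasing_r2": [],
        "swr": [],
        "het_phased": [],
        "het_correct": [],
    }
    for i in range(fam.size):
        pred = (phased.paternal[i], phased.maternal[i])
        truth = (truth_pat[i], truth_mat[i])
        per_ind["phasing_r2"].append(r2_haplotypes(pred, truth))
        per_ind["swr"].append(switch_error_rate(pred, truth))
        per_ind["het_phased"].append(het_phased_fraction(pred, truth))
        per_ind["het_correct"].append(het_correct_fraction(pred, truth))

    return {
        "sire": fam.sire,
        "family_size": fam.size,
        "block_r2": block_r2(result.block_result.blocks, tb),
        "sire_r2": r2_genotypes(result.sire.genotype, sim.truth.sire_genotypes[fam.sire]),
        "pct_imputed": percent_imputed(result.sire),
        "phasing_r2": float(np.nanmean(per_ind["phasing_r2"])),
        "swr": float(np.nanmean(per_ind["swr"])),
        "het_phased": float(np.nanmean(per_ind["het_phased"])),
        "het_correct": float(np.nanmean(per_ind["het_correct"])),
        "n_events": len(result.block_result.events),
        "n_flagged_errors": len(result.block_result.suspected_errors),
    }


def family_size_sweep(
    sim: SimResult,
    sizes: tuple[int, ...] = (4, 8, 40),
    window: int = 30,
    confirm: int = 3,
    rule: str = "dosage",
) -> EvaluationReport:
    """Run the pipeline at several family sizes over one simulated population.

    Each simulated family of N offspring contributes floor(N / size) disjoint
    sub-families per requested size.
    """
    rows = []
    for fam in sim.families:
        truth_blocks = sim.truth.blocks[fam.sire]
        for size in sizes:
            n_sub = fam.size // size
            for s in range(n_sub):
                sub, _ = subsample_family(fam, truth_blocks, size, start=s * size)
                result = phase_pipeline(sub, window=window, confirm=confirm, rule=rule)
                rows.append(evaluate_family(result, sim))
    return EvaluationReport(pd.DataFrame(rows))


def run_benchmark(
    n_markers: int,
    error_rate: float,
    sizes: tuple[int, ...],
    n_families: int = 20,
    seed: int = 0,
    **cfg_overrides,
) -> tuple[SimResult, EvaluationReport]:
    """Simulate one population and sweep family sizes.

    Defaults follow the reference livestock design: 500 cM chromosome,
    multi-generation random mating with a small sire pool, 40 offspring per
    recorded family, and founder markers all segregating at frequency 0.5
    (the historical-population convention of livestock simulators; the
    recent generations then drift the spectrum).
    """
    cfg = SimConfig(
        n_markers=n_markers,
        n_sires=n_families,
        n_dams=max(20 * n_families, n_families),
        founder_freq=cfg_overrides.pop("founder_freq", 0.5),
        error_rate=error_rate,
        seed=seed,
        **cfg_overrides,
    )
    sim = simulate_population(cfg)
    report = family_size_sweep(sim, sizes=sizes)
    return sim, report


def summarize_by_size(report: EvaluationReport) -> pd.DataFrame:
    """Mean of each statistic per family size."""
    return report.rows.groupby("family_size").mean(numeric_only=True)
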