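"""Evaluation statistics: orientation-matched R², switch error rate, block
accuracy and a random-phasing baseline.

Because the two sire strands (and the paternal/maternal labels of a phased
pair) are arbitrary, predicted haplotypes are matched to truth over both
possible pairings and the better one is scored.  All statistics return
``nan`` where undefined (constant vectors, too few usable loci).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .blocking import U, BlockMatrix
from .sire import ALLELE_MISSING, PhasedFamily

_HAP_MISSING = ALLELE_MISSING


def _squared_corr(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2:
        return float("nan")
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0:
        return float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r


def r2_haplotypes(
    pred: tuple[np.ndarray, np.ndarray], truth: tuple[np.ndarray, np.ndarray]
) -> float:
    """Orientation-matched squared correlation between a predicted and a true
    haplotype pair.

    The two predicted haplotypes are concatenated against both pairings of the
    true pair; loci missing in the prediction are omitted; the larger squared
    product-moment correlation is returned (nan if undefined for both).
    """
    p = np.concatenate([np.asarray(h) for h in pred]).astype(float)
    best = float("nan")
    for order in ((0, 1), (1, 0)):
        t = np.concatenate([np.asarray(truth[k]) for k in order]).astype(float)
        if p.shape != t.shape:
            raise ValueError("predicted and true haplotypes differ in length")
        keep = (p != _HAP_MISSING) & (t != _HAP_MISSING)
        r2 = _squared_corr(p[keep], t[keep])
        if np.isnan(best) or (not np.isnan(r2) and r2 > best):
            best = r2
    return best


def switch_error_rate(
    pred: tuple[np.ndarray, np.ndarray], truth: tuple[np.ndarray, np.ndarray]
) -> float:
    """Switch error rate for one individual.

    Computed over loci heterozygous in truth and phased heterozygous in the
    prediction: the number of adjacent locus pairs whose relative phase flips
    between prediction and truth, divided by (number of such loci − 1).
    Invariant to a global swap of the predicted pair.  ``nan`` with fewer
    than two usable loci.
    """
    pp, pm = (np.asarray(h) for h in pred)
    tp, tm = (np.asarray(h) for h in truth)
    usable = (
        (tp != _HAP_MISSING) & (tm != _HAP_MISSING) & (tp != tm)
        & (pp != _HAP_MISSING) & (pm != _HAP_MISSING) & (pp != pm)
    )
    if usable.sum() < 2:
        return float("nan")
    agree = (pp[usable] == tp[usable]).astype(np.int8)
    return float((agree[1:] != agree[:-1]).sum() / (len(agree) - 1))


def het_phased_fraction(
    pred: tuple[np.ndarray, np.ndarray], truth: tuple[np.ndarray, np.ndarray]
) -> float:
    """Fraction of truth-heterozygous loci with a non-missing predicted paternal allele."""
    tp, tm = (np.asarray(h) for h in truth)
    het = (tp != _HAP_MISSING) & (tm != _HAP_MISSING) & (tp != tm)
    if het.sum() == 0:
        return float("nan")
    return float((np.asarray(pred[0])[het] != _HAP_MISSING).mean())


def het_correct_fraction(
    pred: tuple[np.ndarray, np.ndarray], truth: tuple[np.ndarray, np.ndarray]
) -> float:
    """Per-site concordance of phased heterozygous alleles after orientation matching.

    Among truth-het loci phased heterozygous in the prediction, the fraction
    whose paternal allele matches truth, maximised over the global pairing of
    the predicted pair (per individual per chromosome).
    """
    pp, pm = (np.asarray(h) for h in pred)
    tp, tm = (np.asarray(h) for h in truth)
    usable = (
        (tp != _HAP_MISSING) & (tm != _HAP_MISSING) & (tp != tm)
        & (pp != _HAP_MISSING) & (pm != _HAP_MISSING) & (pp != pm)
    )
    if usable.sum() == 0:
        return float("nan")
    match = float((pp[usable] == tp[usable]).mean())
    return max(match, 1.0 - match)


def block_r2(blocks: BlockMatrix, truth: BlockMatrix) -> float:
    """Squared correlation between inferred and true strand-of-origin matrices.

    Strand codes are encoded 0/1, unknown cells in the inferred matrix (or
    truth) are omitted, and the squared product-moment correlation is taken
    over all retained cells of the family jointly — which makes the value
    invariant to a global P<->M relabeling.  ``nan`` with no usable cells.
    """
    if blocks.codes.shape != truth.codes.shape:
        raise ValueError("block matrices differ in shape")
    keep = (blocks.codes != U) & (truth.codes != U)
    return _squared_corr(
        blocks.codes[keep].astype(float), truth.codes[keep].astype(float)
    )


def r2_genotypes(pred: np.ndarray, truth: np.ndarray, missing: int = 9) -> float:
    """Squared correlation between imputed and true genotype vectors over imputed loci."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    keep = (pred != missing) & (truth != missing)
    return _squared_corr(pred[keep].astype(float), truth[keep].astype(float))


def family_phasing_r2(
    phased: PhasedFamily, truth_pat: np.ndarray, truth_mat: np.ndarray
) -> float:
    """Mean orientation-matched haplotype R² over the offspring of one family."""
    vals = [
        r2_haplotypes(
            (phased.paternal[i], phased.maternal[i]), (truth_pat[i], truth_mat[i])
        )
        for i in range(len(phased.individuals))
    ]
    return float(np.nanmean(vals)) if vals else float("nan")


def random_phase_baseline(
    genotypes: np.ndarray,
    truth_pat: np.ndarray,
    truth_mat: np.ndarray,
    repeats: int,
    rng: np.random.Generator,
    missing: int = 9,
) -> float:
    """Mean haplotype R² of coin-flip phasing against truth.

    Each heterozygous genotype is phased by a fair coin, homozygotes
    deterministically; repeated ``repeats`` times and averaged over repeats
    and individuals.  Sets the chance baseline for orientation-matched R².
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    g = np.atleast_2d(np.asarray(genotypes))
    tp = np.atleast_2d(np.asarray(truth_pat))
    tm = np.atleast_2d(np.asarray(truth_mat))
    means = []
    for _ in range(repeats):
        pat = np.full(g.shape, _HAP_MISSING, dtype=np.int8)
        hom = (g == 0) | (g == 2)
        pat[hom] = g[hom] // 2
        het = g == 1
        pat[het] = rng.integers(0, 2, int(het.sum()), dtype=np.int8)
        mat = np.full(g.shape, _HAP_MISSING, dtype=np.int8)
        ok = (g != missing) & (pat != _HAP_MISSING)
        mat[ok] = (g[ok] - pat[ok]).astype(np.int8)
        vals = [
            r2_haplotypes((pat[i], mat[i]), (tp[i], tm[i])) for i in range(g.shape[0])
        ]
        means.append(np.nanmean(vals))
    return float(np.mean(means))


@dataclass
class EvaluationReport:
    """Per-family evaluation rows with an aggregate view."""

    rows: pd.DataFrame

    def aggregate(self) -> pd.DataFrame:
        """Mean ± SD across families for every numeric column."""
        numeric = self.rows.select_dtypes("number")
        return pd.DataFrame({"mean": numeric.mean(), "sd": numeric.std()})

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)
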