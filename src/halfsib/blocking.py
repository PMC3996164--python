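"""Sire strand-of-origin block partitioning for half-sib families.

Within a paternal half-sib family, any marker at which one offspring is
homozygous 0 and another homozygous 2 proves the sire heterozygous there
(*opposing homozygotes*).  At such informative loci every homozygous offspring
reveals which of the sire's two strands it inherited.  Scanning informative
loci left to right with a *forward memory vector* (FMV) of per-offspring
strand labels, and always choosing the strand orientation that implies the
fewest switches against the FMV, partitions each offspring's chromosome into
blocks of constant sire-strand origin.  Implied switches are validated against
downstream informative loci so that isolated genotyping errors do not create
spurious recombination events.

Strand labels ``P`` and ``M`` are arbitrary per chromosome: only their
alternation (the block structure) is meaningful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data import MISSING, GenotypeMatrix, HalfSibFamily

logger = logging.getLogger("halfsib")

#: Block codes: the two sire strands and "unknown".
P: int = 0
M: int = 1
U: int = -1

_CODE_CHAR = {P: "P", M: "M", U: "U"}
_CHAR_CODE = {"P": P, "M": M, "U": U, "-": U}


@dataclass
class BlockMatrix:
    """Offspring x markers matrix of sire-strand codes {P, M, U}."""

    individuals: list[str]
    markers: list[str]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.individuals), len(self.markers)):
            raise ValueError("block matrix shape mismatch")
        if not np.isin(self.codes, (P, M, U)).all():
            raise ValueError("block codes must be in {P, M, U}")

    def to_chars(self) -> np.ndarray:
        out = np.empty(self.codes.shape, dtype="U1")
        for code, ch in _CODE_CHAR.items():
            out[self.codes == code] = ch
        return out

    @classmethod
    def from_chars(
        cls, individuals: list[str], markers: list[str], chars: np.ndarray
    ) -> "BlockMatrix":
        codes = np.full(chars.shape, U, dtype=np.int8)
        for ch, code in _CHAR_CODE.items():
            codes[chars == ch] = code
        return cls(individuals, markers, codes)


@dataclass
class RecombinationEvent:
    """A validated sire-strand switch in one offspring.

    ``left``/``right`` are marker indices of the flanking loci informative for
    that offspring (half-open interval: the crossover lies in
    ``[left, right)`` between them); ``from_strand``/``to_strand`` are block
    codes.
    """

    offspring: str
    left: int
    right: int
    from_strand: int
    to_strand: int

    def __post_init__(self) -> None:
        if not self.left < self.right:
            raise ValueError("event interval must satisfy left < right")


@dataclass
class BlockResult:
    """Output of :func:`block_partition`."""

    blocks: BlockMatrix
    events: list[RecombinationEvent]
    suspected_errors: list[tuple[str, int]]  # (offspring id, marker index)
    sire_het: np.ndarray  # boolean mask over markers
    warnings: list[str] = field(default_factory=list)


def find_sire_het_loci(fam: HalfSibFamily) -> np.ndarray:
    """Boolean mask of markers with opposing homozygotes among the half-sibs.

    True exactly where both homozygote codes 0 and 2 occur among non-missing
    offspring genotypes, proving the sire heterozygous at that marker.
    """
    if fam.size < 2:
        raise ValueError("need at least 2 half-sibs to find informative loci")
    g = fam.genotypes.values
    return (g == 0).any(axis=0) & (g == 2).any(axis=0)


def robust_sire_het_loci(fam: HalfSibFamily) -> np.ndarray:
    """Informative-locus mask robust to genotyping errors in large families.

    Like :func:`find_sire_het_loci`, but in families large enough that a
    genuine sire-het locus essentially never shows only one or two homozygotes
    on the minority side, loci with such minimal minorities are treated as
    error artefacts (a 1% error rate turns a few percent of sire-homozygous
    loci into false opposing-homozygote sites, which otherwise corrupt the
    strand assignment).  For small families every opposing-homozygote locus
    is kept — there the minority side is legitimately small.
    """
    n = fam.size
    if n < 8:
        return find_sire_het_loci(fam)
    g = fam.genotypes.values
    minority = 3 if n >= 32 else 2
    return ((g == 0).sum(axis=0) >= minority) & ((g == 2).sum(axis=0) >= minority)


def pair_recombination(
    pair_a: tuple[int, int], pair_b: tuple[int, int]
) -> bool:
    """Whether two half-sibs' homozygous genotypes at two sire-het loci imply a
    recombination between the loci in one of them.

    All four genotypes must be homozygous (0 or 2).  A recombination is implied
    iff the sum of the four codes is 2 or 6 — equivalently, the pair opposes at
    exactly one of the two loci.
    """
    codes = (*pair_a, *pair_b)
    if any(c not in (0, 2) for c in codes):
        raise ValueError(f"pair_recombination requires homozygous genotypes, got {codes}")
    return sum(codes) in (2, 6)


def count_strand_switches(fmv: np.ndarray, candidate: np.ndarray) -> int:
    """Number of positions where two strand-code vectors are both known and differ."""
    fmv = np.asarray(fmv)
    candidate = np.asarray(candidate)
    if fmv.shape != candidate.shape:
        raise ValueError("vectors must have equal length")
    return int(((fmv != U) & (candidate != U) & (fmv != candidate)).sum())


def _candidate_vectors(
    fmv: np.ndarray, hom0: np.ndarray, hom2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """The two possible strand-assignment vectors at an informative locus and
    their switch counts against the forward memory vector."""
    n = len(fmv)
    v1 = np.full(n, U, dtype=np.int8)
    v1[hom0] = P
    v1[hom2] = M
    v2 = np.full(n, U, dtype=np.int8)
    v2[hom0] = M
    v2[hom2] = P
    return v1, v2, count_strand_switches(fmv, v1), count_strand_switches(fmv, v2)


def _choose_orientation(
    fmv: np.ndarray, last_update: np.ndarray, hom0: np.ndarray, hom2: np.ndarray
) -> np.ndarray:
    """The candidate strand vector implying fewer switches against the FMV.

    Ties are broken in favour of the candidate agreeing with the most recently
    updated FMV entries, then in favour of the orientation assigning P to
    homozygous-0 offspring.  (Used for the one-step orientation estimates
    inside switch validation; the main pass additionally resolves ties by
    validating the implied switches.)
    """
    v1, v2, s1, s2 = _candidate_vectors(fmv, hom0, hom2)
    if s1 != s2:
        return v1 if s1 < s2 else v2
    known = fmv != U
    w1 = int(last_update[known & (v1 == fmv)].sum())
    w2 = int(last_update[known & (v2 == fmv)].sum())
    if w1 != w2:
        return v1 if w1 > w2 else v2
    return v1


def _validate_switch(
    g: np.ndarray,
    cols: np.ndarray,
    idx_t: int,
    i: int,
    fmv: np.ndarray,
    last_update: np.ndarray,
    old: int,
    new: int,
    window: int,
    confirm: int,
) -> tuple[bool, int, int]:
    """Look ahead to confirm an implied strand switch for offspring ``i``.

    Scans up to ``window`` subsequent informative loci at which ``i`` is
    homozygous (the triggering locus counts as the first supporter).  At each
    scanned locus the strand orientation is estimated from the *other*
    offspring's current FMV entries; evidence comes only from cleanly
    anchored loci — one orientation must be clearly consistent with those
    entries.  Every anchored entry disagrees with exactly one candidate
    (s1 + s2 = anchored), so a falsely informative locus (genotyping error
    creating opposing homozygotes where the sire is homozygous) splits the
    entries near-evenly and is excluded as carrying no signal.

    Accepts once ``confirm`` loci support the new strand; rejects once
    ``confirm`` support the old strand; a scan that runs off the chromosome
    end with unanimous support is accepted (late crossover).  ``window == 0``
    disables validation.  Returns (accepted, support, oppose); the margin is
    used to arbitrate orientation ties.
    """
    if window == 0:
        return True, 1, 0
    support, oppose = 1, 0  # the triggering locus supports the switch
    if support >= confirm:
        return True, support, oppose
    others = np.arange(len(fmv)) != i
    fmv_others = np.where(others, fmv, U).astype(np.int8)
    scanned = 1
    idx = idx_t + 1
    while idx < len(cols) and scanned < window:
        j = cols[idx]
        gi = g[i, j]
        if gi not in (0, 2):
            idx += 1
            continue
        scanned += 1
        col = g[:, j]
        hom0 = (col == 0) & others
        hom2 = (col == 2) & others
        v1, v2, s1, s2 = _candidate_vectors(fmv_others, hom0, hom2)
        anchored = s1 + s2
        s_min = min(s1, s2)
        if anchored > 0 and s_min <= anchored // 4:
            chosen = v1 if s1 < s2 else v2
            if hom0.any():
                zero_is_p = chosen[np.flatnonzero(hom0)[0]] == P
            else:
                zero_is_p = chosen[np.flatnonzero(hom2)[0]] == M
            strand_i = P if ((gi == 0) == zero_is_p) else M
            if strand_i == new:
                support += 1
                if support >= confirm:
                    return True, support, oppose
            elif strand_i == old:
                oppose += 1
                if oppose >= confirm:
                    return False, support, oppose
        idx += 1
    return (oppose == 0 and idx >= len(cols)), support, oppose


def block_partition(
    fam: HalfSibFamily, window: int = 30, confirm: int = 3
) -> BlockResult:
    """Partition each half-sib's chromosome into sire-strand blocks.

    Parameters
    ----------
    fam
        Single-chromosome half-sib family, markers in map order.
    window
        Number of downstream informative loci scanned to validate an implied
        strand switch (0 disables validation and accepts every switch).
    confirm
        Informative loci that must support the new strand before a switch is
        accepted; a rejected switch is recorded as a suspected genotyping
        error instead.

    Returns
    -------
    BlockResult
        Block matrix (codes extend to both chromosome ends; the gap strictly
        between the flanks of each accepted switch stays ``U``), validated
        recombination events, and suspected-error cells.
    """
    if window < 0 or confirm < 1 or (window and window < confirm):
        raise ValueError("need window >= confirm >= 1 (or window == 0)")
    g = fam.genotypes.values
    n, n_markers = g.shape
    warnings: list[str] = []
    if fam.size < 4:
        msg = f"family {fam.sire}: only {fam.size} half-sibs; blocks will be unreliable"
        warnings.append(msg)
        logger.warning(msg)

    het = robust_sire_het_loci(fam)
    cols = np.flatnonzero(het)
    blocks = np.full((n, n_markers), U, dtype=np.int8)
    if len(cols) == 0:
        msg = f"family {fam.sire}: no opposing-homozygote loci; family uninformative"
        warnings.append(msg)
        logger.warning(msg)
        return BlockResult(
            BlockMatrix(list(fam.offspring), list(fam.genotypes.markers), blocks),
            [], [], het, warnings,
        )

    # single forward pass: at every informative locus choose the orientation
    # implying fewer switches against the FMV; validate each implied switch by
    # lookahead, restoring the FMV entry when a switch is rejected so that a
    # spurious flip cannot entrench the running strand assignment.  Offspring
    # seeded at a locus with no already-calibrated homozygote form their own
    # provisional component whose P/M labelling is arbitrary; when such a
    # component first meets the calibrated frame, relabelling it wholesale is
    # free and is preferred over charging it with strand switches.
    events: list[RecombinationEvent] = []
    errors: list[tuple[str, int]] = []
    fmv = np.full(n, U, dtype=np.int8)
    last_update = np.zeros(n, dtype=np.int64)
    segments: list[list[tuple[int, int]]] = [[] for _ in range(n)]  # (marker, strand)

    parent = list(range(n))  # union-find over calibration components

    def _find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def _union(a: int, b: int) -> None:
        ra, rb = _find(a), _find(b)
        if ra != rb:
            parent[ra] = rb

    def _flip_component(root: int) -> None:
        for i in range(n):
            if fmv[i] != U and _find(i) == root:
                fmv[i] = 1 - fmv[i]
                segments[i] = [(m, 1 - s if s != U else s) for m, s in segments[i]]
        ident = {fam.offspring[i] for i in range(n) if _find(i) == root}
        for k, ev in enumerate(events):
            if ev.offspring in ident:
                events[k] = RecombinationEvent(
                    ev.offspring, ev.left, ev.right, 1 - ev.from_strand, 1 - ev.to_strand
                )

    for idx, j in enumerate(cols):
        col = g[:, j]
        hom0 = col == 0
        hom2 = col == 2
        hom_idx = np.flatnonzero(hom0 | hom2)
        v1, v2, s1, s2 = _candidate_vectors(fmv, hom0, hom2)
        validated: dict[tuple[int, int, int], tuple[bool, int, int]] = {}

        def _check(i: int, old: int, new: int) -> tuple[bool, int, int]:
            key = (i, old, new)
            if key not in validated:
                validated[key] = _validate_switch(
                    g, cols, idx, i, fmv, last_update, old, new, window, confirm
                )
            return validated[key]

        if s1 != s2:
            chosen = v1 if s1 < s2 else v2
        elif s1 > 0:
            # tie with implied switches either way: let the downstream data
            # arbitrate -- prefer the candidate whose implied switches carry
            # the stronger supporting evidence
            scores = []
            for v in (v1, v2):
                flips = np.flatnonzero((fmv != U) & (v != U) & (v != fmv))
                margin = 0
                for i in flips:
                    _, support, oppose = _check(int(i), int(fmv[i]), int(v[i]))
                    margin += support - oppose
                scores.append(margin)
            if scores[0] != scores[1]:
                chosen = v1 if scores[0] > scores[1] else v2
            else:
                chosen = _choose_orientation(fmv, last_update, hom0, hom2)
        else:
            chosen = _choose_orientation(fmv, last_update, hom0, hom2)

        # relabel provisional components meeting the frame for the first time:
        # a component whose members at this locus all disagree with the chosen
        # orientation, and which shares no component with any agreeing
        # calibrated offspring, flips wholesale instead of switching strands
        known_hom = [int(i) for i in hom_idx if fmv[i] != U]
        agree_roots = {_find(i) for i in known_hom if chosen[i] == fmv[i]}
        if agree_roots:
            flip_roots = {
                _find(i) for i in known_hom if chosen[i] != fmv[i]
            } - agree_roots
            for root in flip_roots:
                _flip_component(root)

        for i in hom_idx:
            new = int(chosen[i])
            old = int(fmv[i])
            if old == U or new == old:
                fmv[i] = new
            elif _check(int(i), old, new)[0]:
                events.append(
                    RecombinationEvent(fam.offspring[i], segments[i][-1][0], int(j), old, new)
                )
                fmv[i] = new
            else:
                errors.append((fam.offspring[i], int(j)))  # fmv restored: code unchanged
            segments[i].append((int(j), int(fmv[i])))
            last_update[i] = idx + 1
        for i in hom_idx[1:]:
            _union(int(i), int(hom_idx[0]))

    for i in range(n):
        segs = segments[i]
        if not segs:
            continue  # heterozygous/missing at every informative locus: all-U row
        # paint the row: back-fill to chromosome start, carry forward between
        # same-strand informative loci, leave switch gaps unknown, extend to end
        first_locus, first_strand = segs[0]
        blocks[i, : first_locus + 1] = first_strand
        for (la, sa), (lb, sb) in zip(segs[:-1], segs[1:]):
            if sa == sb:
                blocks[i, la : lb + 1] = sa
            else:
                blocks[i, lb] = sb  # gap (la, lb) stays U
        blocks[i, segs[-1][0] :] = segs[-1][1]

    return BlockResult(
        BlockMatrix(list(fam.offspring), list(fam.genotypes.markers), blocks),
        events,
        errors,
        het,
        warnings,
    )


def fill_uncertain_codes(blocks: BlockMatrix, end_fill: bool = True) -> BlockMatrix:
    """Fill unknown codes from agreeing flanking codes of the same individual.

    A run of ``U`` whose left and right non-U flanks agree takes that code.
    Runs with disagreeing flanks (recombination gaps) stay ``U``.  Runs at a
    chromosome end have a single flank and are filled from it when
    ``end_fill`` is true.
    """
    codes = blocks.codes.copy()
    for row in codes:
        known = np.flatnonzero(row != U)
        if len(known) == 0:
            continue
        if end_fill:
            row[: known[0]] = row[known[0]]
            row[known[-1] + 1 :] = row[known[-1]]
        for a, b in zip(known[:-1], known[1:]):
            if b - a > 1 and row[a] == row[b]:
                row[a + 1 : b] = row[a]
    return BlockMatrix(list(blocks.individuals), list(blocks.markers), codes)


def apply_error_correction(
    genotypes: GenotypeMatrix, suspected_errors: list[tuple[str, int]]
) -> GenotypeMatrix:
    """Return a copy of the genotypes with suspected-error cells set to missing."""
    values = genotypes.values.copy()
    index = {ind: k for k, ind in enumerate(genotypes.individuals)}
    for ind, j in suspected_errors:
        values[index[ind], j] = MISSING
    return GenotypeMatrix(list(genotypes.individuals), list(genotypes.markers), values)
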