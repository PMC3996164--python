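# Methods

## Model and assumptions

A paternal half-sib family consists of offspring sharing one sire, each out
of a different, unrelated and ungenotyped dam. Every offspring chromosome is
a mosaic of the sire's two homologous strands, switching at the crossovers of
the sire's meiosis; the maternal chromosome is an independent draw from the
dam population. The method assumes biallelic markers in map order on a single
chromosome (multi-chromosome data is processed per chromosome), genotypes
coded 0/1/2 with 9 for missing, and no selection or mutation within the
family. Which homozygote is coded 0 versus 2 is irrelevant: every statistic
is invariant to relabelling, and the strand labels P/M are arbitrary per
chromosome.

## Block partitioning

An *informative* locus has both homozygote codes among the half-sibs, which
proves the sire heterozygous there. The partition is a single forward pass
over informative loci with a per-offspring *forward memory vector* (FMV) of
strand labels:

1. At each informative locus the two possible strand assignments (allele 0
   from strand P, or the complement) are scored by the number of strand
   switches they imply against the FMV; the cheaper one is kept.
   Non-informative loci and heterozygous/missing offspring carry their
   previous label.
2. Every implied switch is validated by scanning up to `window` (default 30)
   subsequent informative loci at which that offspring is homozygous. The
   orientation at a scanned locus is estimated from the *other* offspring's
   FMV entries, and only cleanly anchored loci count as evidence (see error
   handling). `confirm` (default 3) supporting loci, counting the triggering
   locus, accept the switch as a recombination event; `confirm` opposing loci
   reject it and flag the triggering genotype as a suspected error, restoring
   the FMV so a spurious flip cannot entrench itself. A scan that runs off
   the chromosome end with unanimous support is accepted — a genuine late
   crossover has no further loci to confirm it, at the cost that an error at
   the very last informative locus is indistinguishable from one.
3. Orientation ties (equal switch counts both ways) are arbitrated by the
   same lookahead: the candidate whose implied switches carry the larger
   support-minus-opposition margin wins; residual ties fall back to agreeing
   with the most recently updated FMV entries.
4. Offspring seeded at loci where no already-calibrated offspring is
   homozygous form a provisional component whose labelling is arbitrary;
   when such a component first meets the calibrated frame it is relabelled
   wholesale (free) rather than charged with switches. Union–find tracks the
   components.

The block matrix extends each offspring's first and last assignments to the
chromosome ends and leaves unknown (`U`) only the interval strictly between
the flanks of each accepted switch — the region where the crossover actually
is. `fill_uncertain_codes` fills unknown runs whose flanks agree (and
single-flank end runs by default), leaving recombination gaps unknown.

### Identifiability limits

Two configurations are unresolvable for any forward method and bound the
accuracy at small family sizes: (a) simultaneous crossovers in every locally
informative offspring within one uninformative gap flip the whole frame
invisibly; (b) a crossover that precedes an offspring's first informative
homozygote is indistinguishable from the alternative seeding. Both shrink
rapidly with family size, which is why block accuracy climbs steeply from
families of 4 to families of ~10. A frame flip affects every offspring
coherently, so it devastates the block R² while leaving the strand *groups* —
and hence sire imputation and most phasing — intact. The exhaustive-minimum
property (total strand changes equal to the minimum consistent with the
homozygous constraints, verified against an exact dynamic program over
per-offspring strand states) therefore holds exactly in the identifiable
regime and cannot hold outside it.

### Genotyping-error handling

A 1% error rate turns a few percent of sire-homozygous loci into false
opposing-homozygote sites whose "orientation" is noise. Two defenses:

- in families of ≥8 a genuine informative locus essentially never has only
  one (or, at ≥32, two) homozygotes on the minority side, so such loci are
  excluded from the partition (`robust_sire_het_loci`); the public
  `find_sire_het_loci` keeps the unfiltered definition;
- validation evidence only comes from loci where one orientation is cleanly
  consistent with the other offspring's FMV entries (minority disagreement
  ≤ anchored/4); a false locus splits the entries near-evenly and is ignored.

Suspected errors are reported (offspring, marker); `apply_error_correction`
optionally rewrites them to missing in a copy — the input is never mutated.

## Sire imputation and phasing

For each marker and strand, the allele is the mean allele dosage
(genotype/2) of the non-missing offspring assigned to that strand, rounded
to 0/1; an exact 0.5 mean or an empty group stays missing, so no information
is fabricated. Averaging dosages rather than raw genotype codes matters: the
raw-code mean exceeds 0.5 whenever the dams' allele frequency does,
regardless of the sire allele, and would miscall every 0-allele strand at a
common-allele marker. The raw-code rule and a homozygous-offspring-only rule
remain available via `rule=`. Loci proven sire-heterozygous whose two strands
nevertheless impute the same allele are flagged as conflicts and set missing.

Phasing: homozygous offspring loci are phased trivially from the observed
genotype (this is what every phasing tool reports and what the haplotype R²
is dominated by); heterozygous loci take the sire-haplotype allele selected
by the block code; maternal = genotype − paternal where that is a valid
allele. Block-implied alleles contradicting an observed homozygote are
recorded as inconsistencies (a genotyping-error signal) and the observed
genotype wins.

## Simulator

`simulate_population` emulates a commercial-livestock design on a single
chromosome of `map_length_cm` (default 500 cM ≈ a long livestock chromosome)
with `n_markers` evenly spaced markers:

- **Founders** draw allele 1 at marker j with probability p_j, shared across
  founders. `founder_freq="uniform"` draws p_j ~ U(0,1); the dataset-style
  benchmark configs use `founder_freq=0.5`, the historical-population
  convention of livestock simulators, whose markers all segregate at
  intermediate frequency before the recent generations drift them apart.
- **Burn-in** (default 10 generations) is random mating in an unstructured
  population of the same census size, building linkage disequilibrium
  without a sire bottleneck.
- **Recent generations** (default 16) mate `n_sires` males (default 20) to
  `n_dams` females (default 400); the recorded generation forms `n_sires`
  half-sib families of `offspring_per_sire` (default 40), each sire's dams
  drawn without replacement from its share of the dam pool (round-robin
  litters when families exceed the pool, yielding occasional full sibs as in
  a 20-sire/400-dam/40-offspring design).
- **Meiosis** draws the crossover count Poisson with mean = map length in
  Morgans (Haldane, no interference) or uniform on {0..max}; positions are
  i.i.d. uniform; the gamete alternates parental strands from a fair-coin
  start. Truth records both haplotypes per individual, the paternal gamete's
  strand-of-origin per marker (the true block matrix) and all crossover
  positions.
- **Errors**: `inject_errors` rewrites ⌊rate × cells⌋ distinct non-missing
  cells to a uniformly random different code and returns the cell list.

What the simulator does *not* emulate: marker ascertainment against a real
chip, mutation, selection, non-uniform recombination maps, and family
structure on the dam side. Accuracies measured here therefore transfer to
real data only to the extent that informative-locus density (driven by sire
heterozygosity, ~0.4 under the benchmark configs) matches the array used.

## Evaluation statistics

- `block_r2`: squared correlation between inferred and true strand matrices
  over cells known in both, automatically invariant to global relabelling.
- `r2_haplotypes`: squared correlation between concatenated predicted and
  true haplotype pairs, loci missing in the prediction omitted, maximised
  over the two pairings (per individual per chromosome).
- `switch_error_rate`: incorrect phase switches between adjacent usable
  heterozygous sites divided by (usable het sites − 1); invariant to a global
  swap.
- `het_phased_fraction` / `het_correct_fraction`: share of truth-het loci
  phased, and the per-site concordance of the phased ones after orientation
  matching.
- `random_phase_baseline`: coin-flip phasing of het sites (homozygotes
  deterministic); a pure function of the heterozygosity fraction that sets
  the chance floor for haplotype R².

## Benchmark problem sizes

The benchmark/acceptance runs use 20 half-sib families of 40 per simulated
population (subsampled into disjoint sub-families of 4 and 8, giving 200 and
100 replicates of the small sizes), 1250 or 10 000 markers on 500 cM, and
1000 repeats for the random-phasing baseline on a 10-sire × 200-dam,
10-generation population. A full acceptance run takes about three minutes on
one core.

## Known limitations

- Families below ~8 offspring sit partly outside the identifiable regime;
  block R² is then dominated by rare family-coherent frame flips (high
  variance, low mean), although phasing R² stays high because homozygous
  loci and intact strand groups carry it.
- Double crossovers between adjacent informative loci are invisible.
- Maternal haplotypes are reconstructed only by subtraction; no dam-side
  pedigree is used.
- The minority-count filter that protects large families from false
  informative loci is a binomial argument, not a calibrated error model; at
  extreme error rates (≫1%) the validation window should be widened.
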