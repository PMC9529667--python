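# Methods

## Scientific model

CPD formation requires two adjacent same-strand pyrimidines whose
C5–C6 double bonds are close enough, and well enough aligned, for the
[2+2] cycloaddition. The package quantifies that susceptibility with
two step-level descriptors:

- **distance** `d` (Å): Euclidean distance between the midpoints of the
  two C5–C6 bonds (each midpoint the componentwise mean of the C5 and
  C6 coordinates);
- **improper torsion** θ (degrees): the dihedral over the ordered atom
  path 5′C5 → 5′C6 → 3′C6 → 3′C5, reported as a magnitude in
  [0°, 180°]. The sign of a dihedral flips under reflection and the
  favorable/unfavorable dichotomy in the literature is a magnitude
  statement, so the unsigned angle is the meaningful observable.

Small `d` and small θ are the damage-prone geometry. In nucleosomes
both descriptors are expected to oscillate with the ~10 bp helical
repeat because DNA bending around the histone octamer compresses and
over-winds the duplex periodically; the analysis tests whether that
oscillation — rather than DNA mobility — tracks where CPDs actually
form.

Mobility is measured by the crystallographic isotropic B-factor of the
sugar-phosphate backbone: per residue, the unweighted mean over the 11
backbone atom names (P, OP1, OP2, O5′, C5′, C4′, O4′, C3′, O3′, C2′,
C1′), using only atoms present (no imputation). Because absolute
B-factor scales differ across structures and methods, a per-structure
z-score `B_Norm` (sample sd, n−1) is provided alongside raw means, and
compendium aggregates are computed for both.

Damage is summarized as CPD enrichment
`E(k) = (cellular(k)/Σ cellular) / (naked(k)/Σ naked)` over dyad
offsets `k`, where both tracks are lesion counts aligned to a map of
nucleosome dyads. The window-total normalization makes E ≈ 1 inside
the window when chromatin has no effect and renders E invariant to
sequencing depth. Offsets with zero naked coverage are reported as
missing, never infinite, and are dropped from correlations.

## Coordinate conventions

- Chains are indexed 0-based, 5′→3′, gap-free regardless of author
  numbering; the antiparallel geometry of duplex strands is absorbed
  by this convention (so strand-aligned averaging is a positionwise
  mean with an optional register shift, with no explicit reversal).
- The dyad of a chain defaults to its central residue,
  `floor((L−1)/2)`; even-length chains are logged. Because real
  deposited structures can have asymmetric overhangs, a per-structure
  override table (structure_id, chain_id, dyad_index) is the supported
  path for curated dyads.
- Per-nucleotide measures live on integer offsets (default window
  [−73, +73]); per-step measures live on half-integer offsets
  (window [−73.5, +73.5]), the step at residues +10/+11 sitting at
  +10.5. The two conventions are never interpolated into each other;
  enrichment is therefore computed under both lesion-assignment
  conventions (midpoint/half-integer for geometry comparisons, both-
  bases/integer for B-factor comparisons).
- Lesion counts are keyed to the lesion's 5′ pyrimidine. On the minus
  strand the 3′ partner lies at the next lower genomic coordinate, so
  the half-integer midpoint is p − 0.5 and the integer convention
  duplicates the count to p and p − 1.
- Dyad symmetrization folds −k and +k into k ≥ 0; for count-derived
  profiles the fold is weighted by naked read counts, for structural
  profiles it is unweighted (each chain already contributes equally).

## Rotational settings

Minor-in/minor-out boundaries are data, not code: a bundled TSV maps
every offset in [−73.5, +73.5] (0.5 bp granularity) to minor_out,
minor_in or in_between. The default encodes a 10.17 bp phasing with
minor-out at the dyad — band centers {0, ±10, ±20, ±31, ±41, ±51,
±61, ±71} (out) and {±5, ±15, ±26, ±36, ±46, ±56, ±66} (in), each
±1 bp — which places the observed CPD peaks at positions 0 and 10 on
minor-out settings. Users replicating a specific phasing can drop in
their own table.

## Statistics

- **Periodicity**: classical Scargle-normalized Lomb–Scargle power on
  mean-centered values over a period grid of 5–25 bp, step 0.01 bp
  (periods in this domain are conventionally quoted to two decimals).
  The peak's significance comes from a seeded permutation null
  (positions shuffled; default 10,000 permutations, default seed 42),
  `p = (1 + #{max perm power ≥ observed}) / (N + 1)` — assumption-free
  and reproducible. SNR is peak power over mean power outside a
  ±0.5 bp band around the peak; this definition is a package choice
  and is configurable. Zero-variance profiles yield all-zero power,
  no peak, p = 1.
- **Correlation**: Pearson r over shared finite offsets, two-sided p
  from the t-distribution with n−2 df.
- **Quartile table**: pooled (all structures, chains, positions)
  distance and torsion distributions are cut at the 25th/75th
  percentiles (linear interpolation). Five groups are analysed —
  low-low, low-high, mid-mid, high-low, high-high (mixed mid
  combinations excluded) — each observation being the enrichment value
  at a step's half-integer offset, treated as independent. One-way
  ANOVA plus Tukey HSD (statsmodels) compare the groups; empty groups
  drop out with a log message.

## Synthetic generators

`HelixSpec`/`build_helix` place an idealized nucleotide atom template
(hand-built, B-form-like cylindrical geometry: C5–C6 bond 1.34 Å,
bond-midpoint radius ~4 Å) on a straight helical axis with per-step
twist `t(i) = twist0 + twist_amp·cos(2πi/period + phase)` (defaults
36.0°, 3.38 Å rise) and per-residue
`B(i) = B0 + A·cos(2πi/bfactor_period)`, plus optional isotropic
coordinate noise. At the default twist the generated step distances
(~4.1–4.3 Å) and torsions (~36–46°) fall in the range observed in real
nucleosomal DNA, so downstream thresholds operate at realistic scales.
The axis is deliberately straight: twist modulation alone produces the
periodic distance/torsion signal the downstream stages consume, and
superhelical wrapping would add geometry without exercising more code.
Consequently the generator does *not* emulate groove-width variation,
sequence-dependent base-step energetics, or real crystallographic
noise structure — passing tests demonstrate correctness of the
computational chain, not structural realism of any single number.

`DamageSimSpec`/`gen_damage_data` draw a random genome (default
pyrimidine fraction 0.5), enumerate every dipyrimidine site on both
strands, and sample naked counts ~ Poisson(coverage) and cellular
counts ~ Poisson(coverage · E*(k)) with
`E*(k) = 1 + amp·cos(2πk/period + phase)` inside each dyad window and
1 outside. Defaults (500 regularly spaced dyads, amplitude 0.3, period
10.15 bp, coverage 5) give a clearly detectable but noise-limited
photofootprint at desk scale — hundreds of aggregated counts per
offset, i.e. a few-percent relative Poisson error. Real CPD-seq
features not emulated: sequence-composition bias between dipyrimidine
classes, mappability gaps, fuzzy nucleosome positioning, and repair.

Both generators are seeded and byte-deterministic; ground-truth tables
(per-step twist, per-residue B, E*(k)) are written alongside outputs.

## Numerical and design choices

- PDB/mmCIF parsing via gemmi, first model only (each entry is treated
  as one conformation); altloc groups collapse to the highest-occupancy
  conformer, ties to the lexicographically first altloc.
- DNA detection maps standard and common modified residue names to a
  parent base (table is user-extendable); unmapped residues split a
  chain and the longest segment is kept; minimum chain length 40 nt
  rejects ligands while admitting fiber fragments.
- The compendium resolution filter is inclusive (≤ 3.50 Å by default);
  records without a stated resolution are dropped with a log message.
- Degenerate inputs: flat B-factor profiles refuse z-scoring; collinear
  C5–C6 geometry yields an undefined-torsion signal and the step is
  skipped and logged; steps missing any of the four atoms are skipped,
  never imputed.
- Dihedrals use the atan2 formulation (numerically stable near 0° and
  180°); geometry is rigid-motion invariant to ~1e−11 over 147-mer
  scale coordinates.
- Quartile cuts use linear-interpolation percentiles; no outlier
  rejection anywhere in the geometry pipeline (all computed steps enter
  averages).
- The permutation count in bundled tests and the acceptance script is
  reduced (≤ 999) from the library default of 10,000; the smallest
  resolvable p is then 1/(N+1), which the affected checks account for.

## Known limitations

- The center-of-chain dyad default can be wrong for structures with
  asymmetric overhangs; use the override table when replicating curated
  analyses.
- B-factor scales are not comparable across refinement protocols;
  cross-structure aggregates of raw B should be read qualitatively
  (B_Norm exists for this reason).
- The rotational-setting table is a phasing model, not a per-structure
  geometric calculation of groove orientation; computing groove facing
  directly from coordinates would be a natural extension.
- Lomb–Scargle on a 147-point window has limited resolution near 10 bp
  (~±0.05 bp at the grid scale); quoted peak periods inherit that
  uncertainty.
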