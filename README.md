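# photofoot

Structural analysis of UV-damage susceptibility in nucleosomes.

UV light forms cyclobutane pyrimidine dimers (CPDs) by [2+2]
cycloaddition between the C5–C6 double bonds of adjacent same-strand
pyrimidines. In nucleosomes CPD formation is ~10 bp periodic (the
*photofootprint*): elevated where the DNA minor groove faces away from
the histone octamer (minor-out), suppressed where it faces inward
(minor-in). `photofoot` implements the structural analysis that asks
*why*: is it DNA mobility, or the static DNA conformation imposed by
bending around the octamer?

The package is a library for scientists working with nucleosome
structure compendia and genome-wide damage maps. From nucleosome
coordinate files (PDB/mmCIF) and per-position CPD lesion counts it
computes:

- **Mobility** — per-residue mean B-factor over the 11 DNA backbone
  atoms (P, OP1, OP2, O5′, C5′, C4′, O4′, C3′, O3′, C2′, C1′), the
  per-structure z-score `B_Norm = (B − ⟨B⟩)/σ_B`, and strand-aligned
  averaging for multi-nucleosome fibers.
- **CPD geometry** — for every dipyrimidine step, the distance *d*
  between the two C5–C6 bond midpoints and the improper torsion angle
  θ ∈ [0°, 180°] over the atom path 5′C5 → 5′C6 → 3′C6 → 3′C5,
  assigned to half-integer dyad offsets (residues +10/+11 → +10.5).
- **Dyad frame** — mapping of all measures to offsets from the
  nucleosome dyad, weighted symmetrization across the dyad,
  minor-in / minor-out / in-between rotational-setting classification
  (editable data table), and compendium-wide aggregation.
- **CPD enrichment** — `E(k) = (cellular(k)/Σcellular) /
  (naked(k)/Σnaked)` from dyad-aligned lesion counts of a UV-irradiated
  cellular sample and a naked-DNA control; E ≈ 1 when chromatin has no
  effect.
- **Statistics** — classical normalized Lomb–Scargle periodograms over
  5–25 bp with seeded permutation significance, Pearson correlations
  between profiles, and the five-way quartile × quartile
  (distance × torsion) comparison of enrichment with one-way ANOVA and
  Tukey HSD.
- **Synthetic ground truth** — generators for idealized helical
  structures with implanted twist/B-factor modulation and for damage
  tracks with implanted dyad-phased enrichment, so every stage can be
  validated against known inputs.

## Worked example

`examples/03_cpd_enrichment.py` simulates CPD-seq-like counts for 500
nucleosomes with a 10.15 bp enrichment implanted at amplitude 0.3 and
coverage 5, then recovers the enrichment profile:

```
500 dyads, 186024 naked lesions in the window
mean E = 1.0022 (expected ~1); mean |E - E*| = 0.0344
enrichment periodogram: peak = 10.15 bp (implanted 10.15), p = 0.001
symmetrized profile covers offsets 0.5 .. 73.5
```

The mean enrichment sits at ~1 (depth normalization), the per-offset
deviation from the implanted curve E\* is at the Poisson noise floor,
and the periodogram recovers the implanted 10.15 bp photofootprint
period with the smallest p the 999-permutation test can resolve.

`examples/04_full_pipeline.py` runs everything end to end on three
synthetic structures plus damage data implanted in antiphase to the
geometry modulation:

```
record counts: {"structures": 3, "chains": 3, "steps": 200, "dyads": 300}
        distance: peak 10.00 bp, p = 0.002
         torsion: peak 10.00 bp, p = 0.002
  cpd_enrichment: peak 10.00 bp, p = 0.002
corr(distance, E): r = -0.992, p = 3.51e-64
corr(torsion, E): r = -0.992, p = 3.78e-64
quartile means: {'low_low': 1.28, 'mid_mid': 0.955, 'high_high': 0.754}
```

Both geometry measures carry the implanted 10 bp period and correlate
negatively with enrichment — low distance + low torsion marks the
damage-prone conformation — and the quartile table orders
low-low > mid-mid > high-high accordingly.

A thin CLI mirrors the library (`photofoot --help`): subcommands
`simulate-structure`, `simulate-damage`, `geometry`, `mobility`,
`enrich`, `periodogram`, `correlate`, `quartiles`, `run-all`.

## Layout

```
src/photofoot/
  structure_io.py       PDB/mmCIF parsing, compendium filter, dyad assignment
  mobility.py           backbone B-factor, B_Norm, strand-aligned averaging
  photogeometry.py      C5-C6 midpoint distance + improper torsion per step
  nucleosome_frame.py   dyad offsets, symmetrization, rotational settings
  damage_enrichment.py  lesion assignment, dyad alignment, E(k)
  periodicity_stats.py  Lomb-Scargle, Pearson, quartile ANOVA/Tukey
  synthetic_data.py     ground-truth generators (helix, damage tracks)
  pipeline.py / cli.py  orchestration and the thin command-line front end
  data/                 rotational-setting table, synthetic atom template
```

See `docs/methods.md` for the model, parameter defaults, numerical
choices, and what the synthetic generators do and do not emulate.
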