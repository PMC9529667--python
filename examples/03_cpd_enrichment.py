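"""CPD enrichment from damage-count tracks.

Simulates CPD-seq-like lesion counts for a UV-irradiated cellular
sample and a naked-DNA control over 500 synthetic nucleosomes with an
implanted 10.15 bp dyad-phased enrichment, then recovers the
enrichment profile E(k) and its periodicity.
"""

import tempfile
from pathlib import Path

import numpy as np

from photofoot import (DamageSimSpec, assign_lesions, dyad_align, enrichment,
                       gen_damage_data, lomb_scargle, symmetrize)

spec = DamageSimSpec(n_dyads=500, enrichment_amp=0.3,
                     enrichment_period=10.15, mean_coverage=5.0, seed=3)
with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    cellular, naked, dyads = gen_damage_data(
        spec, tmp / "cellular.tsv", tmp / "naked.tsv", tmp / "dyads.tsv")

cell_aligned = dyad_align(assign_lesions(cellular, "half_integer"), dyads,
                          window=spec.window)
naked_aligned = dyad_align(assign_lesions(naked, "half_integer"), dyads,
                           window=spec.window)
e = enrichment(cell_aligned, naked_aligned)

e_true = spec.true_enrichment(e.offsets)
print(f"{len(dyads)} dyads, {int(naked_aligned.values.sum())} naked lesions "
      f"in the window")
print(f"mean E = {np.nanmean(e.values):.4f} (expected ~1); "
      f"mean |E - E*| = {np.nanmean(np.abs(e.values - e_true)):.4f}")

pg = lomb_scargle(e, n_permutations=999, seed=3)
print(f"enrichment periodogram: peak = {pg.peak_period:.2f} bp "
      f"(implanted 10.15), p = {pg.p_value:.4g}")

e_sym = symmetrize(e, weighted=True)
print(f"symmetrized profile covers offsets 0.5 .. {e_sym.offsets[-1]:g}")

# E(k) ~ 1 means chromatin has no effect at that offset; the recovered
# ~10 bp periodicity is the nucleosome photofootprint implanted by the
# generator.
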