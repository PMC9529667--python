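"""DNA mobility (B-factor) profile and its periodicity.

Builds a synthetic helix whose per-residue B-factor carries an
implanted 10 bp cosine, extracts the backbone B-factor profile,
z-scores it per structure (B_Norm), and measures the periodicity with
a Lomb-Scargle periodogram.
"""

import numpy as np

from photofoot import (HelixSpec, backbone_bfactor, build_helix, lomb_scargle,
                       normalize_bfactor)
from photofoot.nucleosome_frame import PositionProfile

spec = HelixSpec(n_bp=147, bfactor_base=40.0, bfactor_amp=5.0,
                 bfactor_period=10.0, seed=2)
record, truth = build_helix(spec)
chain = record.dna_chains[0]
dyad = record.dyad_index["A"]

raw = backbone_bfactor(chain)
bnorm = normalize_bfactor(raw)
zvals = np.array(list(bnorm.values.values()))
print(f"B_Norm identity: mean = {zvals.mean():.2e}, sd = {zvals.std(ddof=1):.6f}")

profile = PositionProfile.from_mapping(
    "bfactor", {pos - dyad: v for pos, v in raw.values.items()})
pg = lomb_scargle(profile, n_permutations=999, seed=2)
print(f"B-factor periodogram: peak period = {pg.peak_period:.2f} bp, "
      f"SNR = {pg.snr:.1f}, permutation p = {pg.p_value:.4g}")

# The implanted 10 bp mobility modulation is recovered exactly; in real
# nucleosome structures the same analysis reports how strongly backbone
# mobility follows the helical repeat.
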