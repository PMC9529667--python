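"""End-to-end pipeline run on a synthetic fixture set.

Generates three structures (10 bp twist + B-factor modulation) and a
matching damage data set whose enrichment is implanted in antiphase to
the geometry modulation, then runs the full pipeline: parsing,
mobility, geometry, dyad alignment, enrichment, periodograms,
correlations and the quartile table.
"""

import json
import tempfile
from pathlib import Path

import numpy as np

from photofoot import (DamageSimSpec, HelixSpec, RunConfig, gen_damage_data,
                       gen_helix_structure, run_pipeline)

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    paths = []
    for seed in range(3):
        spec = HelixSpec(n_bp=147, twist_amp=2.0, period=10.0,
                         phase=-np.pi / 2, pyrimidine_fraction=0.7,
                         bfactor_amp=5.0, seed=seed)
        p, _ = gen_helix_structure(spec, tmp / f"helix{seed}.pdb")
        paths.append(str(p))
    dspec = DamageSimSpec(n_dyads=300, enrichment_amp=0.3,
                          enrichment_period=10.0, enrichment_phase=np.pi,
                          mean_coverage=5.0, seed=4)
    gen_damage_data(dspec, tmp / "cellular.tsv", tmp / "naked.tsv",
                    tmp / "dyads.tsv")

    config = RunConfig(
        structure_paths=paths,
        cellular_track=str(tmp / "cellular.tsv"),
        naked_track=str(tmp / "naked.tsv"),
        dyad_map=str(tmp / "dyads.tsv"),
        n_permutations=499,
        outdir=str(tmp / "out"),
        seed=4,
    )
    bundle = run_pipeline(config)

    print("record counts:", json.dumps(bundle["manifest"]["counts"]))
    for name, pg in bundle["periodograms"].items():
        print(f"{name:>16s}: peak {pg.peak_period:.2f} bp, p = {pg.p_value:.4g}")
    for name, c in bundle["correlations"].items():
        print(f"corr({name}, E): r = {c['r']:+.3f}, p = {c['p_value']:.3g}")
    qt = bundle["quartiles"]
    means = qt.group_means()
    print("quartile means:",
          {k: round(v, 3) for k, v in means.items() if np.isfinite(v)})

# The distance/torsion periodograms recover the implanted 10 bp twist
# period; because the enrichment was implanted in antiphase, both
# geometry measures correlate negatively with E — the direction the
# method is built to detect.
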