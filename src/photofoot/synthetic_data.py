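"""Desk-scale synthetic inputs with known ground truth.

Two generators emulate the pipeline's real inputs:

* :func:`gen_helix_structure` — an idealized straight-axis DNA helix
  written as a PDB file, with a tunable ~10 bp periodic modulation of
  the helical twist (which propagates into the dipyrimidine C5-C6
  distance/torsion profiles) and an implanted cosine B-factor profile.
* :func:`gen_damage_data` — cellular and naked lesion-count tracks over
  a synthetic genome plus a dyad map, with a dyad-phased periodic
  enrichment E*(k) implanted into the cellular track and Poisson
  counting noise in both.

Both write plain-text files identical in format to real inputs, plus a
ground-truth table sufficient to score every downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .structure_io import AtomRecord, NucleotideRecord, StructureRecord, write_pdb

__all__ = ["HelixSpec", "DamageSimSpec", "build_helix", "gen_helix_structure",
           "gen_damage_data", "load_template"]

PYRIMIDINES = frozenset("CT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def load_template() -> dict[str, tuple[np.ndarray, str]]:
    """Bundled idealized nucleotide template: atom -> (local xyz, applies)."""
    ref = resources.files("photofoot.data").joinpath("bdna_template.tsv")
    with resources.as_file(ref) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    return {str(r.atom): (np.array([r.x, r.y, r.z]), str(r.applies))
            for r in df.itertuples()}


@dataclass
class HelixSpec:
    """Parameters of the synthetic helical structure.

    Defaults are canonical B-DNA (36.0° mean twist, 3.38 Å rise) over a
    147 bp nucleosome-length chain; ``twist_amp``/``period`` implant a
    periodic twist modulation and ``bfactor_*`` implant a cosine
    mobility profile.
    """

    n_bp: int = 147
    sequence: str | None = None
    pyrimidine_fraction: float = 0.5
    rise: float = 3.38
    twist0: float = 36.0
    twist_amp: float = 0.0
    period: float = 10.0
    phase: float = 0.0
    coord_noise_sd: float = 0.0
    bfactor_base: float = 40.0
    bfactor_amp: float = 0.0
    bfactor_period: float = 10.0
    resolution: float = 2.00
    seed: int = 0

    def validate(self):
        if self.n_bp < 2:
            raise ValueError("n_bp must be >= 2")
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        if self.period <= 0 or self.bfactor_period <= 0:
            raise ValueError("periods must be positive")
        if self.twist0 + self.twist_amp >= 360:
            raise ValueError("twist exceeds a full turn")
        if self.sequence is not None and len(self.sequence) != self.n_bp:
            raise ValueError("sequence length must equal n_bp")
        if self.coord_noise_sd < 0:
            raise ValueError("coord_noise_sd must be nonnegative")
        if self.bfactor_base - abs(self.bfactor_amp) < 0:
            raise ValueError("B-factors must stay nonnegative")


def _random_sequence(rng: np.random.Generator, n: int, pyr_frac: float) -> str:
    p = [(1 - pyr_frac) / 2, pyr_frac / 2, (1 - pyr_frac) / 2, pyr_frac / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def build_helix(spec: HelixSpec) -> tuple[StructureRecord, pd.DataFrame]:
    """Construct the synthetic helix in memory.

    Residue i sits at cumulative twist Θ(i) = Σ_{j<i} t(j) with per-step
    twist t(j) = twist0 + twist_amp·cos(2πj/period + phase), and at
    height i·rise on a straight axis. Atoms come from the bundled
    template rotated into that frame; B(i) = bfactor_base +
    bfactor_amp·cos(2πi/bfactor_period). Returns the structure plus a
    ground-truth table of per-step twist and per-residue B-factor.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    template = load_template()
    seq = spec.sequence or _random_sequence(rng, spec.n_bp, spec.pyrimidine_fraction)

    idx = np.arange(spec.n_bp)
    step_twist = spec.twist0 + spec.twist_amp * np.cos(
        2 * np.pi * idx / spec.period + spec.phase)
    theta = np.deg2rad(np.concatenate([[0.0], np.cumsum(step_twist[:-1])]))
    bfac = spec.bfactor_base + spec.bfactor_amp * np.cos(
        2 * np.pi * idx / spec.bfactor_period)

    residues = []
    for i in range(spec.n_bp):
        cos_t, sin_t = np.cos(theta[i]), np.sin(theta[i])
        atoms = {}
        for name, (local, applies) in template.items():
            if applies == "pyrimidine" and seq[i] not in PYRIMIDINES:
                continue
            x, y, z = local
            pos = np.array([x * cos_t - y * sin_t,
                            x * sin_t + y * cos_t,
                            z + i * spec.rise])
            if spec.coord_noise_sd > 0:
                pos = pos + rng.normal(0, spec.coord_noise_sd, 3)
            atoms[name] = AtomRecord(name=name, position=pos,
                                     bfactor=float(bfac[i]))
        residues.append(NucleotideRecord(chain_id="A", seq_index=i,
                                         base=seq[i], atoms=atoms))
    record = StructureRecord(
        structure_id=f"synthetic_helix_seed{spec.seed}",
        resolution=spec.resolution,
        dna_chains=[residues],
        dyad_index={"A": (spec.n_bp - 1) // 2},
    )
    truth = pd.DataFrame({
        "seq_index": idx,
        "base": list(seq),
        "step_twist_deg": step_twist,
        "bfactor": bfac,
    })
    return record, truth


def gen_helix_structure(
    spec: HelixSpec,
    pdb_path: str | Path,
    truth_path: str | Path | None = None,
) -> tuple[Path, Path | None]:
    """Write the synthetic helix as a PDB file plus a ground-truth TSV."""
    record, truth = build_helix(spec)
    pdb_path = Path(pdb_path)
    write_pdb(record, pdb_path)
    tpath = None
    if truth_path is not None:
        tpath = Path(truth_path)
        with open(tpath, "w") as fh:
            fh.write(f"# synthetic helix ground truth\tseed={spec.seed}\n")
            truth.to_csv(fh, sep="\t", index=False, float_format="%.6f")
    return pdb_path, tpath


# ---------------------------------------------------------------------------
# damage-track simulation

@dataclass
class DamageSimSpec:
    """Parameters of the synthetic CPD-seq-like count tracks.

    Defaults emulate the real study's conditions at desk scale: 500
    strongly positioned dyads, a ~10.15 bp dyad-phased enrichment of
    modest amplitude inside the 147 bp core, and a mean naked coverage
    of 5 lesions per dipyrimidine site.
    """

    genome_length: int | None = None
    n_dyads: int = 500
    spacing: int = 200
    enrichment_amp: float = 0.3
    enrichment_period: float = 10.15
    enrichment_phase: float = 0.0
    mean_coverage: float = 5.0
    window: float = 73.5
    pyrimidine_fraction: float = 0.5
    chrom: str = "chrSim"
    seed: int = 0

    def validate(self):
        if self.n_dyads < 1 or self.spacing < 1:
            raise ValueError("n_dyads and spacing must be positive")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be positive")
        if self.enrichment_period <= 0:
            raise ValueError("enrichment_period must be positive")
        if self.enrichment_amp < 0 or self.enrichment_amp >= 1:
            raise ValueError("enrichment_amp must lie in [0, 1)")
        margin = int(self.window) + 2
        needed = self.n_dyads * self.spacing + 2 * margin
        if self.genome_length is not None and self.genome_length < needed:
            raise ValueError(f"genome_length must be >= {needed}")

    @property
    def margin(self) -> int:
        return int(self.window) + 2

    def dyad_positions(self) -> np.ndarray:
        return self.margin + self.spacing * np.arange(self.n_dyads)

    def length(self) -> int:
        return self.genome_length or (self.n_dyads * self.spacing + 2 * self.margin)

    def true_enrichment(self, k: np.ndarray | float) -> np.ndarray:
        """Implanted E*(k): 1 + amp·cos(2πk/period + phase) inside the
        dyad window, exactly 1 outside."""
        k = np.asarray(k, dtype=float)
        e = 1.0 + self.enrichment_amp * np.cos(
            2 * np.pi * k / self.enrichment_period + self.enrichment_phase)
        return np.where(np.abs(k) <= self.window, e, 1.0)


def gen_damage_data(
    spec: DamageSimSpec,
    cellular_path: str | Path,
    naked_path: str | Path,
    dyad_path: str | Path,
    truth_path: str | Path | None = None,
):
    """Simulate cellular/naked CPD count tracks over a synthetic genome.

    A seeded random sequence is drawn; every dipyrimidine site on both
    strands (keyed to its 5' pyrimidine) receives naked counts
    ~ Poisson(mean_coverage) and cellular counts ~ Poisson(mean_coverage
    · E*(k)), where k is the site midpoint's offset from the nearest
    dyad. Zero counts are written explicitly (they carry coverage
    information). Returns (cellular_track, naked_track, dyad_map) as
    in-memory objects after writing all files.
    """
    from .damage_enrichment import DamageTrack, DyadMap, write_damage_track, \
        write_dyad_map

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.length()
    seq = _random_sequence(rng, n, spec.pyrimidine_fraction)
    arr = np.frombuffer(seq.encode(), dtype="S1")
    is_pyr = (arr == b"C") | (arr == b"T")
    is_pur = ~is_pyr

    dyads = spec.dyad_positions()

    # 5'-keyed dipyrimidine sites: plus strand at 1-based p where bases
    # p, p+1 are pyrimidines; minus strand at p where bases p-1, p are
    # purines (their complements are adjacent pyrimidines, 5' at p).
    plus_idx = np.nonzero(is_pyr[:-1] & is_pyr[1:])[0]          # 0-based
    minus_idx = np.nonzero(is_pur[:-1] & is_pur[1:])[0] + 1
    sites = [(int(i) + 1, "+", float(i) + 1 + 0.5) for i in plus_idx]
    sites += [(int(i) + 1, "-", float(i) + 1 - 0.5) for i in minus_idx]
    sites.sort()

    positions = np.array([m for _, _, m in sites])
    # offset of each site midpoint from its nearest dyad
    nearest = np.clip(np.round((positions - dyads[0]) / spec.spacing), 0,
                      spec.n_dyads - 1).astype(int)
    offsets = positions - dyads[nearest]
    e_true = spec.true_enrichment(offsets)

    naked_counts = rng.poisson(spec.mean_coverage, size=len(sites))
    cell_counts = rng.poisson(spec.mean_coverage * e_true)

    cellular = DamageTrack(
        sample="cellular",
        counts={(spec.chrom, float(p), s): int(c)
                for (p, s, _), c in zip(sites, cell_counts)},
        convention="dipyrimidine_5prime")
    naked = DamageTrack(
        sample="naked",
        counts={(spec.chrom, float(p), s): int(c)
                for (p, s, _), c in zip(sites, naked_counts)},
        convention="dipyrimidine_5prime")
    dyad_map = DyadMap(entries=[(spec.chrom, int(d), "+") for d in dyads])

    write_damage_track(cellular, cellular_path)
    write_damage_track(naked, naked_path)
    write_dyad_map(dyad_map, dyad_path)
    if truth_path is not None:
        ks = np.arange(-spec.window, spec.window + 1.0)
        pd.DataFrame({"offset": ks, "e_true": spec.true_enrichment(ks)}).to_csv(
            truth_path, sep="\t", index=False, float_format="%.8f")
    return cellular, naked, dyad_map
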