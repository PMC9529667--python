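"""DNA mobility profiling from crystallographic B-factors.

The isotropic B-factor of the sugar-phosphate backbone is used as a
proxy for local DNA mobility. Per-residue profiles average the eleven
backbone atoms, per-structure normalization (B_Norm) z-scores the
per-residue means, and strand-aligned averaging combines the two
strands of a (tetra)nucleosome in matching 5'->3' register to remove
translational asymmetry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .structure_io import NucleotideRecord

logger = logging.getLogger(__name__)

__all__ = ["BACKBONE_ATOMS", "BFactorProfile", "backbone_bfactor",
           "normalize_bfactor", "strand_aligned_average"]

#: the eleven DNA backbone atom names contributing to the mobility profile
BACKBONE_ATOMS = ("P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'",
                  "C2'", "C1'")


class DegenerateProfileError(ValueError):
    """The profile has zero variance and cannot be z-scored."""


@dataclass
class BFactorProfile:
    """Per-position mean backbone B-factor (Å²), indexed by seq_index or
    dyad offset, with the count of contributing atoms per position."""

    values: dict[float, float]
    n_atoms: dict[float, int] = field(default_factory=dict)
    normalized: bool = False

    def positions(self) -> list[float]:
        return sorted(self.values)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        pos = np.array(sorted(self.values), dtype=float)
        return pos, np.array([self.values[p] for p in pos])


def backbone_bfactor(chain: list[NucleotideRecord]) -> BFactorProfile:
    """Per-residue unweighted mean B-factor over the backbone atoms
    present in that residue (no imputation for missing atoms).

    Residues with zero backbone atoms are omitted and logged. Base atoms
    (C5, C6, N1, ...) never contribute.
    """
    if not chain:
        raise ValueError("empty chain")
    values: dict[float, float] = {}
    n_atoms: dict[float, int] = {}
    for rec in chain:
        bs = [rec.atoms[a].bfactor for a in BACKBONE_ATOMS if a in rec.atoms]
        if not bs:
            logger.warning("chain %s residue %d: no backbone atoms, omitted",
                           rec.chain_id, rec.seq_index)
            continue
        values[float(rec.seq_index)] = float(np.mean(bs))
        n_atoms[float(rec.seq_index)] = len(bs)
    return BFactorProfile(values=values, n_atoms=n_atoms)


def normalize_bfactor(profile: BFactorProfile) -> BFactorProfile:
    """B_Norm: z-score the per-residue means within one structure,
    using the sample (n-1) standard deviation."""
    pos, vals = profile.as_arrays()
    if len(vals) < 2:
        raise ValueError("need at least 2 residues to normalize")
    mean = vals.mean()
    sd = vals.std(ddof=1)
    if sd == 0:
        raise DegenerateProfileError("zero variance: cannot z-score a flat profile")
    z = (vals - mean) / sd
    return BFactorProfile(
        values={p: float(v) for p, v in zip(pos, z)},
        n_atoms=dict(profile.n_atoms),
        normalized=True,
    )


def strand_aligned_average(
    profile_strand1: BFactorProfile,
    profile_strand2: BFactorProfile,
    shift: int = 0,
) -> BFactorProfile:
    """Average two strands' profiles in 5'->3' register.

    Both inputs are indexed 5'->3' along their own strand (the parser's
    convention), so the antiparallel geometry is already folded out:
    position i of strand 1 is averaged with position i + ``shift`` of
    strand 2. ``shift`` aligns linker registers when the strands have
    staggered overhangs. The strands must cover the same number of
    positions after shifting.
    """
    p1, v1 = profile_strand1.as_arrays()
    p2, v2 = profile_strand2.as_arrays()
    if len(p1) != len(p2):
        raise ValueError(
            f"strand length mismatch after alignment: {len(p1)} vs {len(p2)}")
    strand2 = {float(p - shift): (v, profile_strand2.n_atoms.get(p, 0))
               for p, v in zip(p2, v2)}
    values, n_atoms = {}, {}
    for pos, v in zip(p1, v1):
        pos = float(pos)
        if pos not in strand2:
            raise ValueError(f"no strand-2 value aligned to position {pos:g}")
        v2i, n2i = strand2[pos]
        values[pos] = float((v + v2i) / 2.0)
        n_atoms[pos] = profile_strand1.n_atoms.get(pos, 0) + n2i
    return BFactorProfile(values=values, n_atoms=n_atoms,
                          normalized=profile_strand1.normalized)
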