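"""CPD-susceptibility geometry of dipyrimidine steps.

UV-induced cyclobutane pyrimidine dimers (CPDs) form by [2+2]
cycloaddition between the C5-C6 double bonds of adjacent same-strand
pyrimidines. Two structural parameters gate that reaction: the distance
between the midpoints of the two C5-C6 bonds, and the improper torsion
(dihedral) angle over the four atoms 5'C5, 5'C6, 3'C6, 3'C5 describing
the relative alignment of the two bonds. Small distance and small
torsion are the geometry favorable to dimerization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .structure_io import NucleotideRecord

logger = logging.getLogger(__name__)

__all__ = ["DipyrimidineStep", "c5c6_midpoint", "step_distance",
           "step_torsion", "enumerate_steps",
           "MissingAtomError", "UndefinedTorsionError"]

PYRIMIDINES = frozenset("CT")


class MissingAtomError(ValueError):
    """A required C5 or C6 atom is absent from the residue."""


class UndefinedTorsionError(ValueError):
    """The dihedral is undefined (collinear bond geometry)."""


@dataclass
class DipyrimidineStep:
    """One adjacent same-strand pyrimidine pair and its CPD geometry.

    ``half_pos`` is the step's dyad offset: the mean of the two
    residues' offsets, always a half-integer (e.g. residues at +10 and
    +11 give +10.5).
    """

    structure_id: str
    chain_id: str
    pos5: int
    pos3: int
    bases: str
    distance: float
    torsion: float
    half_pos: float

    def __post_init__(self):
        if self.pos3 != self.pos5 + 1:
            raise ValueError("pos3 must be pos5 + 1")
        if not (0.0 <= self.torsion <= 180.0):
            raise ValueError("torsion must lie in [0, 180] degrees")


def c5c6_midpoint(residue: NucleotideRecord) -> np.ndarray:
    """Midpoint of the C5-C6 bond: componentwise mean of the two atoms."""
    if not residue.has_atoms("C5", "C6"):
        missing = [a for a in ("C5", "C6") if a not in residue.atoms]
        raise MissingAtomError(
            f"chain {residue.chain_id} residue {residue.seq_index}: "
            f"missing {','.join(missing)}")
    return (residue.atoms["C5"].position + residue.atoms["C6"].position) / 2.0


def step_distance(res5: NucleotideRecord, res3: NucleotideRecord) -> float:
    """Euclidean distance (Å) between the C5-C6 bond midpoints of the
    5' and 3' residues of a step."""
    return float(np.linalg.norm(c5c6_midpoint(res5) - c5c6_midpoint(res3)))


def dihedral(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """Signed dihedral angle (degrees, IUPAC convention: 0 = eclipsed)
    over the ordered point path a-b-c-d."""
    b1 = np.asarray(b, float) - np.asarray(a, float)
    b2 = np.asarray(c, float) - np.asarray(b, float)
    b3 = np.asarray(d, float) - np.asarray(c, float)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise UndefinedTorsionError("collinear geometry: dihedral undefined")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    return float(np.degrees(np.arctan2(y, x)))


def step_torsion(res5: NucleotideRecord, res3: NucleotideRecord) -> float:
    """Improper torsion (degrees, magnitude in [0, 180]) of the two
    C5-C6 bonds, over the atom path 5'C5 -> 5'C6 -> 3'C6 -> 3'C5.

    Reported unsigned: the favorable/unfavorable dichotomy is a
    magnitude statement and reflection symmetry makes the sign
    conventional.
    """
    for res in (res5, res3):
        if not res.has_atoms("C5", "C6"):
            missing = [a for a in ("C5", "C6") if a not in res.atoms]
            raise MissingAtomError(
                f"chain {res.chain_id} residue {res.seq_index}: "
                f"missing {','.join(missing)}")
    return abs(dihedral(
        res5.atoms["C5"].position,
        res5.atoms["C6"].position,
        res3.atoms["C6"].position,
        res3.atoms["C5"].position,
    ))


def enumerate_steps(
    chain: list[NucleotideRecord],
    dyad_index: int,
    structure_id: str = "",
) -> list[DipyrimidineStep]:
    """All dipyrimidine steps of a chain with their CPD geometry.

    A step is any adjacent same-strand pair of pyrimidines (C/T) whose
    four C5/C6 atoms are all present; steps with missing atoms or
    degenerate geometry are logged and skipped, never emitted.
    """
    if not 0 <= dyad_index < len(chain):
        raise ValueError(f"dyad index {dyad_index} out of bounds")
    steps = []
    for res5, res3 in zip(chain, chain[1:]):
        if res5.base not in PYRIMIDINES or res3.base not in PYRIMIDINES:
            continue
        try:
            distance = step_distance(res5, res3)
            torsion = step_torsion(res5, res3)
        except (MissingAtomError, UndefinedTorsionError) as exc:
            logger.warning("step %d-%d skipped: %s", res5.seq_index,
                           res3.seq_index, exc)
            continue
        steps.append(DipyrimidineStep(
            structure_id=structure_id,
            chain_id=res5.chain_id,
            pos5=res5.seq_index,
            pos3=res3.seq_index,
            bases=res5.base + res3.base,
            distance=distance,
            torsion=torsion,
            half_pos=((res5.seq_index - dyad_index)
                      + (res3.seq_index - dyad_index)) / 2.0,
        ))
    return steps


def steps_to_profiles(steps: list[DipyrimidineStep]):
    """Per-chain distance and torsion profiles over half-integer offsets.

    Multiple steps at the same offset (never the case within one chain)
    are averaged. Returns (distance_profile, torsion_profile).
    """
    from .nucleosome_frame import PositionProfile

    acc_d: dict[float, list[float]] = {}
    acc_t: dict[float, list[float]] = {}
    for s in steps:
        acc_d.setdefault(s.half_pos, []).append(s.distance)
        acc_t.setdefault(s.half_pos, []).append(s.torsion)
    dist = PositionProfile.from_mapping(
        "distance", {k: float(np.mean(v)) for k, v in acc_d.items()})
    tors = PositionProfile.from_mapping(
        "torsion", {k: float(np.mean(v)) for k, v in acc_t.items()})
    return dist, tors
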