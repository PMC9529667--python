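"""Reading and writing nucleosome coordinate files.

Parses PDB/mmCIF files (via gemmi), extracts DNA chains as ordered
5'->3' nucleotide records with per-atom coordinates and B-factors,
applies the high-resolution compendium filter, and assigns the dyad
base of each chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "NucleotideRecord",
    "StructureRecord",
    "StructureParseError",
    "EmptyStructureError",
    "parse_structure",
    "filter_compendium",
    "assign_dyad",
    "write_pdb",
    "read_structure_list",
    "read_dyad_overrides",
    "chain_inventory",
]

#: canonical deoxynucleotide residue names -> one-letter base
STANDARD_DNA = {"DA": "A", "DC": "C", "DG": "G", "DT": "T"}

#: default mapping of common modified residues to their parent base
DEFAULT_MODIFIED_BASES = {
    "5CM": "C",  # 5-methyl-dC
    "5MC": "C",
    "5HC": "C",  # 5-hydroxymethyl-dC
    "5IU": "T",  # 5-iodo-dU (thymine analogue)
    "BRU": "T",  # 5-bromo-dU
    "UMP": "T",
    "8OG": "G",  # 8-oxo-dG
    "6OG": "G",
    "1AP": "A",
}


class StructureParseError(ValueError):
    """The coordinate file could not be parsed."""


class EmptyStructureError(ValueError):
    """No DNA chain satisfying the length filter was found."""


@dataclass
class AtomRecord:
    """One atom: label, position (Å), isotropic B-factor (Å²)."""

    name: str
    position: np.ndarray
    bfactor: float
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")


@dataclass
class NucleotideRecord:
    """One DNA residue: chain, 0-based 5'->3' index, canonical base, atoms."""

    chain_id: str
    seq_index: int
    base: str
    atoms: dict[str, AtomRecord] = field(default_factory=dict)

    def has_atoms(self, *names: str) -> bool:
        return all(n in self.atoms for n in names)


@dataclass
class StructureRecord:
    """All DNA chains of one structure plus per-chain dyad indices."""

    structure_id: str
    resolution: float | None
    dna_chains: list[list[NucleotideRecord]]
    dyad_index: dict[str, int] = field(default_factory=dict)

    @property
    def chain_ids(self) -> list[str]:
        return [c[0].chain_id for c in self.dna_chains]

    def chain(self, chain_id: str) -> list[NucleotideRecord]:
        for c in self.dna_chains:
            if c[0].chain_id == chain_id:
                return c
        raise KeyError(chain_id)


def normalize_atom_name(name: str) -> str:
    """Normalize prime conventions across dialects (C1' / C1′ / C1*)."""
    return name.strip().replace("′", "'").replace("*", "'")


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties broken by lexicographically first altloc
    return min(atoms, key=lambda a: (-a.occ, a.altloc))


_FORMATS = {
    "pdb": gemmi.CoorFormat.Pdb,
    "mmcif": gemmi.CoorFormat.Mmcif,
    "auto": gemmi.CoorFormat.Detect,
}


def parse_structure(
    path: str | Path,
    format: str = "auto",
    min_chain_length: int = 40,
    modified_bases: dict[str, str] | None = None,
    resolution: float | None = None,
) -> StructureRecord:
    """Parse a coordinate file into a :class:`StructureRecord`.

    Only the first model is read. Residues whose names map to
    deoxynucleotides (standard names plus a configurable modified-base
    table) are kept; an unmapped residue breaks a chain into segments
    and the longest segment is retained, provided it has at least
    ``min_chain_length`` residues. Atom altloc groups are collapsed to
    the highest-occupancy conformer.

    Parameters
    ----------
    path:
        PDB or mmCIF file.
    format:
        ``pdb``, ``mmcif`` or ``auto`` (detect from contents/extension).
    min_chain_length:
        Shortest DNA segment admitted as a chain (rejects ligands).
    modified_bases:
        Residue-name -> parent-base map merged over the built-in table.
    resolution:
        Optional override for the header resolution (Å).
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"{path}: file not found")
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}")
    base_map = dict(STANDARD_DNA)
    base_map.update(DEFAULT_MODIFIED_BASES)
    if modified_bases:
        base_map.update(modified_bases)

    try:
        st = gemmi.read_structure(str(path), format=_FORMATS[format])
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no model in file")

    res_header = resolution
    if res_header is None and st.resolution and st.resolution > 0:
        res_header = float(st.resolution)

    model = st[0]  # first model only
    chains: list[list[NucleotideRecord]] = []
    for chain in model:
        segments: list[list[NucleotideRecord]] = [[]]
        for residue in chain:
            rname = residue.name.strip().upper()
            if rname not in base_map:
                if segments[-1]:
                    segments.append([])  # unmapped residue breaks the chain
                continue
            atoms: dict[str, AtomRecord] = {}
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in residue:
                by_name.setdefault(normalize_atom_name(atom.name), []).append(atom)
            for aname, group in by_name.items():
                a = _pick_altloc(group)
                atoms[aname] = AtomRecord(
                    name=aname,
                    position=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    bfactor=float(a.b_iso),
                    occupancy=float(a.occ),
                    altloc=a.altloc or "",
                )
            segments[-1].append(
                NucleotideRecord(
                    chain_id=chain.name,
                    seq_index=-1,  # assigned after segment selection
                    base=base_map[rname],
                    atoms=atoms,
                )
            )
        best = max(segments, key=len)
        if len(best) < min_chain_length:
            if best:
                logger.debug(
                    "%s chain %s: longest DNA segment has %d residues (< %d), skipped",
                    path.name, chain.name, len(best), min_chain_length,
                )
            continue
        for i, rec in enumerate(best):
            rec.seq_index = i  # gap-free 0-based 5'->3'
        chains.append(best)

    if not chains:
        raise EmptyStructureError(f"{path}: no DNA chain of >= {min_chain_length} nt found")

    record = StructureRecord(
        structure_id=path.stem,
        resolution=res_header,
        dna_chains=chains,
    )
    for c in chains:
        record.dyad_index[c[0].chain_id] = assign_dyad(c)
    return record


def filter_compendium(
    records: list[StructureRecord], max_resolution: float = 3.50
) -> list[StructureRecord]:
    """Keep structures with resolution <= ``max_resolution`` Å (inclusive).

    Records lacking a resolution are dropped and logged.
    """
    if max_resolution <= 0:
        raise ValueError("max_resolution must be positive")
    kept = []
    for rec in records:
        if rec.resolution is None:
            logger.warning("%s: no resolution in header, dropped from compendium",
                           rec.structure_id)
            continue
        if rec.resolution <= max_resolution:
            kept.append(rec)
    return kept


def assign_dyad(chain: list[NucleotideRecord], override: int | None = None) -> int:
    """Dyad base index of a chain: the central residue, or an explicit override.

    For chain length L the default is ``floor((L - 1) / 2)``; even-length
    chains have no exact center and the floor convention is logged.
    """
    if not chain:
        raise ValueError("empty chain")
    n = len(chain)
    if override is not None:
        if not 0 <= override < n:
            raise ValueError(f"dyad override {override} out of bounds for chain of {n}")
        return override
    if n % 2 == 0:
        logger.warning(
            "chain %s has even length %d: dyad assigned to floor center %d",
            chain[0].chain_id, n, (n - 1) // 2,
        )
    return (n - 1) // 2


# ---------------------------------------------------------------------------
# emission and tabular side inputs

def write_pdb(record: StructureRecord, path: str | Path) -> Path:
    """Write a StructureRecord back to PDB (coordinates %.3f, B-factors %.2f)."""
    path = Path(path)
    lines = []
    if record.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION. {record.resolution:7.2f} ANGSTROMS.")
    serial = 1
    for chain in record.dna_chains:
        for rec in chain:
            resname = "D" + rec.base
            for atom in rec.atoms.values():
                name = atom.name
                # PDB column alignment: 4-char names start in col 13
                padded = f" {name:<3s}" if len(name) < 4 else name
                element = name[0] if name[0].isalpha() else name[1]
                x, y, z = atom.position
                lines.append(
                    f"ATOM  {serial:5d} {padded:<4s}{'':1s}{resname:>3s} "
                    f"{rec.chain_id[:1]:1s}{rec.seq_index + 1:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.bfactor:6.2f}"
                    f"          {element:>2s}"
                )
                serial += 1
        lines.append("TER")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_structure_list(path: str | Path) -> list[tuple[str, float | None]]:
    """Read a structure list file: one path/ID per line, optional
    tab-separated resolution override; '#' lines are comments."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        res = float(parts[1]) if len(parts) > 1 and parts[1] else None
        out.append((parts[0], res))
    return out


def read_dyad_overrides(path: str | Path) -> dict[tuple[str, str], int]:
    """Read the dyad override TSV (structure_id, chain_id, dyad_index)."""
    overrides = {}
    lines = Path(path).read_text().splitlines()
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("structure_id"):
            continue
        sid, cid, idx = line.split("\t")[:3]
        overrides[(sid, cid)] = int(idx)
    return overrides


def chain_inventory(records: list[StructureRecord]) -> list[dict]:
    """Tabular chain inventory (structure, chain, length, dyad, resolution)."""
    rows = []
    for rec in records:
        for chain in rec.dna_chains:
            cid = chain[0].chain_id
            rows.append(
                {
                    "structure_id": rec.structure_id,
                    "chain_id": cid,
                    "length": len(chain),
                    "dyad_index": rec.dyad_index[cid],
                    "resolution": rec.resolution,
                }
            )
    return rows
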