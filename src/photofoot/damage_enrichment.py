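"""CPD enrichment profiles from lesion-count tracks.

Consumes per-position, per-strand CPD lesion counts for a UV-irradiated
cellular sample and a naked-DNA control (counts keyed to the lesion's
5' pyrimidine), assigns lesions to half-integer midpoints or to both
integer positions of the dipyrimidine, aligns counts to a map of
nucleosome dyads, and forms the depth-normalized cellular:naked
enrichment ratio E(k) per dyad offset k (E = 1 when chromatin has no
effect).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nucleosome_frame import PositionProfile

logger = logging.getLogger(__name__)

__all__ = ["DamageTrack", "DyadMap", "assign_lesions", "dyad_align",
           "enrichment", "read_damage_track", "write_damage_track",
           "read_dyad_map", "write_dyad_map"]

#: keying conventions for track positions
CONVENTIONS = ("dipyrimidine_5prime", "half_integer", "integer")


@dataclass
class DamageTrack:
    """Per-genomic-position, per-strand lesion counts for one sample.

    ``counts`` maps (chromosome, position, strand) to a nonnegative
    count; positions are 1-based and may be half-integers after
    midpoint assignment. ``convention`` records how positions are keyed.
    Zero-count entries denote covered sites and matter for the coverage
    weights of :func:`dyad_align`.
    """

    sample: str
    counts: dict[tuple[str, float, str], int] = field(default_factory=dict)
    convention: str = "dipyrimidine_5prime"

    def __post_init__(self):
        if self.convention not in CONVENTIONS:
            raise ValueError(f"unknown keying convention {self.convention!r}")
        for key, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count at {key}")

    def total(self) -> int:
        return sum(self.counts.values())

    def scaled(self, factor: float) -> "DamageTrack":
        return DamageTrack(
            sample=self.sample,
            counts={k: v * factor for k, v in self.counts.items()},
            convention=self.convention,
        )


@dataclass
class DyadMap:
    """Genomic positions of nucleosome dyads: (chrom, pos, orientation)."""

    entries: list[tuple[str, int, str]] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for chrom, pos, orient in self.entries:
            if orient not in ("+", "-"):
                raise ValueError(f"orientation must be + or -, got {orient!r}")
            if (chrom, pos) in seen:
                raise ValueError(f"duplicate dyad {chrom}:{pos}")
            seen.add((chrom, pos))

    def __len__(self) -> int:
        return len(self.entries)


def assign_lesions(track: DamageTrack, convention: str) -> DamageTrack:
    """Re-key 5'-pyrimidine-keyed lesion counts to an analysis convention.

    ``half_integer``: each lesion is recorded once at the midpoint of
    the two pyrimidines (5' position +0.5 on the plus strand, -0.5 on
    the minus strand, which runs 5'->3' toward lower coordinates).
    ``integer``: each lesion is recorded at both pyrimidine positions,
    doubling the total assigned count.
    """
    if convention not in ("half_integer", "integer"):
        raise ValueError(f"unknown convention {convention!r}")
    if track.convention != "dipyrimidine_5prime":
        raise ValueError("track is already assigned; expected 5'-keyed counts")
    counts: dict[tuple[str, float, str], int] = {}

    def add(key, c):
        counts[key] = counts.get(key, 0) + c

    for (chrom, pos, strand), c in track.counts.items():
        step = 1.0 if strand == "+" else -1.0
        if convention == "half_integer":
            add((chrom, pos + 0.5 * step, strand), c)
        else:
            add((chrom, float(pos), strand), c)
            add((chrom, pos + step, strand), c)
    return DamageTrack(sample=track.sample, counts=counts, convention=convention)


def dyad_align(
    track: DamageTrack,
    dyads: DyadMap,
    window: float = 73.5,
) -> PositionProfile:
    """Sum lesion counts into dyad-relative offsets.

    A count at genomic position p contributes to offset p - dyad
    (sign-flipped for minus-oriented dyads); counts from both strands
    are pooled. The offset grid follows the track's keying convention:
    half-integers in [-window, +window] for midpoint-assigned tracks,
    integers otherwise. The weight at each offset is the number of
    dyads with site coverage there (a zero-count entry is coverage).
    """
    if track.convention == "dipyrimidine_5prime":
        raise ValueError("assign_lesions must be applied before dyad_align")
    if window <= 0:
        raise ValueError("window must be positive (symmetric about 0)")
    half = track.convention == "half_integer"
    if half:
        w = np.floor(window - 0.5) + 0.5
        grid = np.arange(-w, w + 1.0)
    else:
        grid = np.arange(-np.floor(window), np.floor(window) + 1.0)

    # per-chromosome position -> summed count over strands, keyed at 2x
    # the position so half-integers index exactly
    per_chrom: dict[str, dict[int, float]] = {}
    for (chrom, pos, _strand), c in track.counts.items():
        d = per_chrom.setdefault(chrom, {})
        key = int(round(pos * 2))
        d[key] = d.get(key, 0) + c

    values = np.zeros_like(grid)
    weights = np.zeros_like(grid)
    for chrom, dpos, orient in dyads.entries:
        sites = per_chrom.get(chrom)
        if sites is None:
            continue
        sign = 1.0 if orient == "+" else -1.0
        for i, k in enumerate(grid):
            key = int(round((dpos + sign * k) * 2))
            if key in sites:
                values[i] += sites[key]
                weights[i] += 1
    return PositionProfile(
        measure="counts", offsets=grid, values=values, weights=weights)


def enrichment(
    cellular: PositionProfile,
    naked: PositionProfile,
) -> PositionProfile:
    """CPD enrichment E(k) = (cellular(k)/Σcellular) / (naked(k)/Σnaked).

    Sums run over the shared analysis window, so a uniform pair gives
    E = 1 everywhere and E is invariant to sequencing depth of either
    track. Offsets with zero naked coverage get NaN (logged), never
    infinity. The output carries naked counts as weights (used for
    read-count-weighted dyad symmetrization).
    """
    if len(cellular) != len(naked) or not np.allclose(cellular.offsets, naked.offsets):
        raise ValueError("cellular and naked profiles must share offsets")
    c = cellular.values.astype(float)
    n = naked.values.astype(float)
    c_tot, n_tot = c.sum(), n.sum()
    if n_tot <= 0:
        raise ValueError("naked track has no counts in the window")
    if c_tot <= 0:
        raise ValueError("cellular track has no counts in the window")
    with np.errstate(divide="ignore", invalid="ignore"):
        e = (c / c_tot) / (n / n_tot)
    bad = n == 0
    if bad.any():
        logger.warning("%d offsets with zero naked coverage emitted as missing",
                       int(bad.sum()))
        e[bad] = np.nan
    return PositionProfile(
        measure="cpd_enrichment",
        offsets=cellular.offsets.copy(),
        values=e,
        weights=n.copy(),
    )


# ---------------------------------------------------------------------------
# text formats

def write_damage_track(track: DamageTrack, path: str | Path) -> Path:
    """TSV with a header line declaring sample and keying convention."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# sample={track.sample}\tkeying={track.convention}\n")
        fh.write("chrom\tpos\tstrand\tcount\n")
        for (chrom, pos, strand), c in sorted(track.counts.items()):
            fh.write(f"{chrom}\t{pos:g}\t{strand}\t{c:g}\n")
    return path


def read_damage_track(path: str | Path) -> DamageTrack:
    path = Path(path)
    sample, convention = "unknown", "dipyrimidine_5prime"
    counts: dict[tuple[str, float, str], int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                for tokens in line[1:].strip().split("\t"):
                    if "=" in tokens:
                        k, v = tokens.split("=", 1)
                        if k.strip() == "sample":
                            sample = v.strip()
                        elif k.strip() == "keying":
                            convention = v.strip()
                continue
            if not line or line.startswith("chrom"):
                continue
            chrom, pos, strand, c = line.split("\t")[:4]
            counts[(chrom, float(pos), strand)] = int(float(c))
    return DamageTrack(sample=sample, counts=counts, convention=convention)


def write_dyad_map(dyads: DyadMap, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("chrom\tpos\torientation\n")
        for chrom, pos, orient in dyads.entries:
            fh.write(f"{chrom}\t{pos}\t{orient}\n")
    return path


def read_dyad_map(path: str | Path) -> DyadMap:
    entries = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("chrom"):
            continue
        parts = line.split("\t")
        orient = parts[2] if len(parts) > 2 and parts[2] else "+"
        entries.append((parts[0], int(parts[1]), orient))
    return DyadMap(entries=entries)
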