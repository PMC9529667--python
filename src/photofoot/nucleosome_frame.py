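"""Dyad-relative coordinate frame for nucleosomal DNA.

Per-chain measures (B-factor, step geometry, lesion counts) are mapped
into offsets relative to the nucleosome dyad, symmetrized across the
dyad (the nucleosome is pseudo-twofold symmetric), classified by
rotational setting (minor-in / minor-out / in-between), and aggregated
across a compendium of structures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PositionProfile",
    "RotationalSettingTable",
    "symmetrize",
    "classify_setting",
    "aggregate_compendium",
    "load_rotational_table",
]

MEASURES = ("bfactor", "bnorm", "distance", "torsion", "cpd_enrichment", "counts")


@dataclass
class PositionProfile:
    """A measure indexed by dyad offset.

    Offsets are integers (per-nucleotide measures, default window
    [-73, +73]) or half-integers (per-dipyrimidine-step measures,
    default window [-73.5, +73.5]); they are strictly increasing.
    ``weights`` holds nonnegative contribution counts (chains, dyads or
    reads depending on the measure). NaN values mark offsets without
    usable data.
    """

    measure: str
    offsets: np.ndarray
    values: np.ndarray
    weights: np.ndarray | None = None
    symmetrized: bool = False

    def __post_init__(self):
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.weights is None:
            self.weights = np.ones_like(self.values)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
        if not (len(self.offsets) == len(self.values) == len(self.weights)):
            raise ValueError("offsets, values and weights must have equal length")
        if len(self.offsets) > 1 and not np.all(np.diff(self.offsets) > 0):
            raise ValueError("offsets must be strictly increasing")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")

    def __len__(self) -> int:
        return len(self.offsets)

    def value_at(self, offset: float) -> float:
        idx = np.nonzero(np.isclose(self.offsets, offset))[0]
        if idx.size == 0:
            return float("nan")
        return float(self.values[idx[0]])

    def dropna(self) -> "PositionProfile":
        mask = np.isfinite(self.values)
        return replace(
            self,
            offsets=self.offsets[mask],
            values=self.values[mask],
            weights=self.weights[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"measure": self.measure, "offset": self.offsets,
             "value": self.values, "weight": self.weights}
        )

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")
        return path

    @classmethod
    def from_tsv(cls, path: str | Path, symmetrized: bool = False) -> "PositionProfile":
        df = pd.read_csv(path, sep="\t")
        return cls(
            measure=str(df["measure"].iloc[0]),
            offsets=df["offset"].to_numpy(),
            values=df["value"].to_numpy(),
            weights=df["weight"].to_numpy() if "weight" in df else None,
            symmetrized=symmetrized,
        )

    @classmethod
    def from_mapping(cls, measure: str, mapping: dict, weights: dict | None = None,
                     symmetrized: bool = False) -> "PositionProfile":
        offs = np.array(sorted(mapping), dtype=float)
        vals = np.array([mapping[k] for k in sorted(mapping)], dtype=float)
        w = None
        if weights is not None:
            w = np.array([weights.get(k, 1.0) for k in sorted(mapping)], dtype=float)
        return cls(measure=measure, offsets=offs, values=vals, weights=w,
                   symmetrized=symmetrized)


def symmetrize(profile: PositionProfile, weighted: bool = False) -> PositionProfile:
    """Fold a profile across the dyad: value(k) for k >= 0 combines the
    values at -k and +k (weighted mean when ``weighted`` is set, else
    unweighted); offset 0 passes through; the combined weight is the sum
    of both sides' weights.
    """
    if profile.symmetrized:
        raise ValueError("profile is already symmetrized")
    lut = {o: i for i, o in enumerate(profile.offsets)}
    out_offsets = sorted({abs(o) for o in profile.offsets})
    values, weights = [], []
    for k in out_offsets:
        idxs = []
        for o in ({k} if k == 0 else {-k, k}):
            if o in lut:
                idxs.append(lut[o])
        vs = profile.values[idxs]
        ws = profile.weights[idxs]
        ok = np.isfinite(vs)
        vs, ws = vs[ok], ws[ok]
        if vs.size == 0:
            values.append(np.nan)
            weights.append(0.0)
        elif weighted and ws.sum() > 0:
            values.append(float(np.average(vs, weights=ws)))
            weights.append(float(ws.sum()))
        else:
            values.append(float(vs.mean()))
            weights.append(float(ws.sum()))
    return PositionProfile(
        measure=profile.measure,
        offsets=np.array(out_offsets, dtype=float),
        values=np.array(values),
        weights=np.array(weights),
        symmetrized=True,
    )


# ---------------------------------------------------------------------------
# rotational settings

#: minor-groove-out band centers (10.17 bp phasing, minor-out at the dyad)
DEFAULT_MINOR_OUT_CENTERS = (0, 10, 20, 31, 41, 51, 61, 71)
#: minor-groove-in band centers
DEFAULT_MINOR_IN_CENTERS = (5, 15, 26, 36, 46, 56, 66)
#: half-width of each band, bp
DEFAULT_HALF_WIDTH = 1.0


@dataclass
class RotationalSettingTable:
    """Offset -> {minor_in, minor_out, in_between} lookup table.

    Rotational-setting boundaries are data, not code: the bundled
    default (10.17 bp phasing, minor-out at the dyad) can be replaced by
    any TSV with columns offset, category.
    """

    categories: dict[float, str] = field(default_factory=dict)

    def __getitem__(self, offset: float) -> str:
        key = round(float(offset) * 2) / 2
        if key not in self.categories:
            raise KeyError(f"offset {offset} outside rotational-setting table")
        return self.categories[key]

    def __contains__(self, offset: float) -> bool:
        return round(float(offset) * 2) / 2 in self.categories

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RotationalSettingTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(categories={float(r.offset): str(r.category)
                               for r in df.itertuples()})

    @classmethod
    def default(cls, window: float = 73.5, step: float = 0.5,
                out_centers=DEFAULT_MINOR_OUT_CENTERS,
                in_centers=DEFAULT_MINOR_IN_CENTERS,
                half_width: float = DEFAULT_HALF_WIDTH) -> "RotationalSettingTable":
        outs = np.array([c * s for c in out_centers for s in ((1,) if c == 0 else (1, -1))])
        ins = np.array([c * s for c in in_centers for s in (1, -1)])
        table = {}
        for off in np.arange(-window, window + step / 2, step):
            off = round(float(off) * 2) / 2
            if np.min(np.abs(outs - off)) <= half_width:
                table[off] = "minor_out"
            elif np.min(np.abs(ins - off)) <= half_width:
                table[off] = "minor_in"
            else:
                table[off] = "in_between"
        return cls(categories=table)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        rows = sorted(self.categories.items())
        with open(path, "w") as fh:
            fh.write("offset\tcategory\n")
            for off, cat in rows:
                fh.write(f"{off:g}\t{cat}\n")
        return path


def load_rotational_table(path: str | Path | None = None) -> RotationalSettingTable:
    """Load a rotational-setting table; default is the bundled TSV."""
    if path is not None:
        return RotationalSettingTable.from_tsv(path)
    ref = resources.files("photofoot.data").joinpath("rotational_settings.tsv")
    with resources.as_file(ref) as p:
        return RotationalSettingTable.from_tsv(p)


def classify_setting(offset: float, table: RotationalSettingTable | None = None) -> str:
    """Rotational setting of a dyad offset: minor_in, minor_out or in_between."""
    if table is None:
        table = load_rotational_table()
    return table[offset]


def aggregate_compendium(profiles: list[PositionProfile]) -> PositionProfile:
    """Positionwise unweighted mean across chains/structures.

    Each input profile (one chain of one structure) contributes equally;
    the output weight at an offset is the number of contributing chains.
    Offsets with zero contributors are omitted.
    """
    if not profiles:
        raise ValueError("no profiles to aggregate")
    measures = {p.measure for p in profiles}
    if len(measures) > 1:
        raise ValueError(f"mixed measures: {sorted(measures)}")
    symm = {p.symmetrized for p in profiles}
    if len(symm) > 1:
        raise ValueError("cannot aggregate symmetrized with unsymmetrized profiles")
    acc: dict[float, list[float]] = {}
    for p in profiles:
        for o, v in zip(p.offsets, p.values):
            if np.isfinite(v):
                acc.setdefault(float(o), []).append(float(v))
    offsets = np.array(sorted(acc), dtype=float)
    values = np.array([np.mean(acc[o]) for o in offsets])
    weights = np.array([len(acc[o]) for o in offsets], dtype=float)
    return PositionProfile(
        measure=profiles[0].measure,
        offsets=offsets,
        values=values,
        weights=weights,
        symmetrized=profiles[0].symmetrized,
    )
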