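"""End-to-end orchestration: structures -> mobility + geometry ->
dyad frame -> (optional) CPD enrichment -> periodicity, correlation and
quartile statistics, with a reproducible manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import damage_enrichment as de
from . import mobility, periodicity_stats, photogeometry, structure_io
from .nucleosome_frame import (PositionProfile, aggregate_compendium,
                               symmetrize)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-loadable; seed recorded
    in every output)."""

    structure_list: str | None = None
    structure_paths: list[str] = field(default_factory=list)
    dyad_override_path: str | None = None
    max_resolution: float = 3.50
    min_chain_length: int = 40
    window: float = 73.5
    convention: str = "half_integer"
    rotational_table_path: str | None = None
    cellular_track: str | None = None
    naked_track: str | None = None
    dyad_map: str | None = None
    period_range: tuple[float, float] = (5.0, 25.0)
    grid_step: float = 0.01
    n_permutations: int = 1000
    seed: int = 42
    outdir: str = "photofoot_out"
    skip_errors: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**data)
        if isinstance(cfg.period_range, list):
            cfg.period_range = tuple(cfg.period_range)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["period_range"] = list(self.period_range)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_structures(config: RunConfig) -> list[structure_io.StructureRecord]:
    paths: list[tuple[str, float | None]] = [(p, None) for p in config.structure_paths]
    if config.structure_list:
        paths += structure_io.read_structure_list(config.structure_list)
    if not paths:
        raise PipelineError("stage structures: no structure inputs configured")
    overrides = {}
    if config.dyad_override_path:
        overrides = structure_io.read_dyad_overrides(config.dyad_override_path)
    records = []
    for path, res in paths:
        try:
            rec = structure_io.parse_structure(
                path, min_chain_length=config.min_chain_length, resolution=res)
        except (structure_io.StructureParseError,
                structure_io.EmptyStructureError) as exc:
            if config.skip_errors:
                logger.warning("stage structures: skipped %s (%s)", path, exc)
                continue
            raise PipelineError(f"stage structures: failed on {path}: {exc}") from exc
        for chain in rec.dna_chains:
            cid = chain[0].chain_id
            key = (rec.structure_id, cid)
            if key in overrides:
                rec.dyad_index[cid] = structure_io.assign_dyad(chain, overrides[key])
        records.append(rec)
    if not records:
        raise PipelineError("stage structures: all inputs failed")
    return structure_io.filter_compendium(records, config.max_resolution)


def _to_offsets(values: dict[float, float], dyad: int) -> dict[float, float]:
    return {p - dyad: v for p, v in values.items()}


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages and write outputs to ``outdir``.

    Returns a result bundle (profiles, periodograms, correlations,
    quartile table, manifest). Rerunning with an identical config
    reproduces identical outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    # --- structures, mobility, geometry ---------------------------------
    records = _load_structures(config)
    counts["structures"] = len(records)
    pd.DataFrame(structure_io.chain_inventory(records)).to_csv(
        outdir / "chain_inventory.tsv", sep="\t", index=False)

    b_profiles, bnorm_profiles, dist_profiles, tors_profiles = [], [], [], []
    all_steps: list[photogeometry.DipyrimidineStep] = []
    for rec in records:
        for chain in rec.dna_chains:
            cid = chain[0].chain_id
            dyad = rec.dyad_index[cid]
            try:
                prof = mobility.backbone_bfactor(chain)
                b_profiles.append(PositionProfile.from_mapping(
                    "bfactor", _to_offsets(prof.values, dyad)))
                try:
                    bnorm = mobility.normalize_bfactor(prof)
                    bnorm_profiles.append(PositionProfile.from_mapping(
                        "bnorm", _to_offsets(bnorm.values, dyad)))
                except mobility.DegenerateProfileError:
                    logger.warning("flat B-factor profile for %s/%s: "
                                   "B_Norm skipped", rec.structure_id, cid)
                steps = photogeometry.enumerate_steps(
                    chain, dyad, structure_id=rec.structure_id)
                all_steps.extend(steps)
                dp, tp = photogeometry.steps_to_profiles(steps)
                if len(dp):
                    dist_profiles.append(dp)
                if len(tp):
                    tors_profiles.append(tp)
            except (ValueError, KeyError) as exc:
                if config.skip_errors:
                    logger.warning("stage profiles: skipped %s/%s (%s)",
                                   rec.structure_id, cid, exc)
                    continue
                raise PipelineError(
                    f"stage profiles: failed on {rec.structure_id}/{cid}: {exc}"
                ) from exc
    counts["chains"] = len(b_profiles)
    counts["steps"] = len(all_steps)

    aggregated: dict[str, PositionProfile] = {}
    symmetric: dict[str, PositionProfile] = {}
    for name, plist in [("bfactor", b_profiles), ("bnorm", bnorm_profiles),
                        ("distance", dist_profiles), ("torsion", tors_profiles)]:
        if not plist:
            continue
        agg = aggregate_compendium(plist)
        aggregated[name] = agg
        symmetric[name] = symmetrize(agg, weighted=True)
        agg.to_tsv(outdir / f"profile_{name}.tsv")
        symmetric[name].to_tsv(outdir / f"profile_{name}_symmetrized.tsv")
    if all_steps:
        pd.DataFrame([dataclasses.asdict(s) for s in all_steps]).to_csv(
            outdir / "dipyrimidine_steps.tsv", sep="\t", index=False,
            float_format="%.6f")

    # --- damage enrichment ----------------------------------------------
    # Enrichment is produced under both lesion-assignment conventions:
    # half-integer offsets pair with step geometry (distance/torsion),
    # integer offsets pair with the per-nucleotide B-factor profiles.
    enrich = None
    enrich_int = None
    if config.cellular_track and config.naked_track and config.dyad_map:
        try:
            cellular_raw = de.read_damage_track(config.cellular_track)
            naked_raw = de.read_damage_track(config.naked_track)
            dyads = de.read_dyad_map(config.dyad_map)

            def _enrich(convention: str, window: float) -> PositionProfile:
                cell = de.dyad_align(
                    de.assign_lesions(cellular_raw, convention), dyads, window)
                nak = de.dyad_align(
                    de.assign_lesions(naked_raw, convention), dyads, window)
                return de.enrichment(cell, nak)

            enrich = _enrich("half_integer", config.window)
            enrich_int = _enrich("integer", np.floor(config.window))
        except (ValueError, OSError) as exc:
            raise PipelineError(f"stage enrichment: {exc}") from exc
        counts["dyads"] = len(dyads)
        enrich.to_tsv(outdir / "profile_cpd_enrichment.tsv")
        enrich_int.to_tsv(outdir / "profile_cpd_enrichment_integer.tsv")
        enrich_sym = symmetrize(enrich, weighted=True)
        enrich_sym.to_tsv(outdir / "profile_cpd_enrichment_symmetrized.tsv")
        aggregated["cpd_enrichment"] = enrich
        symmetric["cpd_enrichment"] = enrich_sym
        symmetric["cpd_enrichment_integer"] = symmetrize(enrich_int, weighted=True)

    # --- statistics ------------------------------------------------------
    periodograms = {}
    for name, prof in aggregated.items():
        pg = periodicity_stats.lomb_scargle(
            prof, period_range=config.period_range, grid_step=config.grid_step,
            n_permutations=config.n_permutations, seed=config.seed)
        periodograms[name] = pg
        pd.DataFrame({"period": pg.periods, "power": pg.power}).to_csv(
            outdir / f"periodogram_{name}.tsv", sep="\t", index=False,
            float_format="%.8g")
    with open(outdir / "periodogram_summary.json", "w") as fh:
        json.dump({
            name: {"peak_period": pg.peak_period, "peak_power": pg.peak_power,
                   "snr": pg.snr, "p_value": pg.p_value,
                   "n_permutations": pg.n_permutations, "seed": pg.seed}
            for name, pg in periodograms.items()}, fh, indent=2, sort_keys=True)

    correlations = {}
    if enrich is not None:
        for name in ("bfactor", "bnorm", "distance", "torsion"):
            if name not in symmetric:
                continue
            esym = (symmetric["cpd_enrichment_integer"]
                    if name in ("bfactor", "bnorm")
                    else symmetric["cpd_enrichment"])
            try:
                res = periodicity_stats.pearson(symmetric[name], esym)
            except ValueError as exc:
                logger.warning("correlation %s vs enrichment skipped: %s",
                               name, exc)
                continue
            correlations[name] = {"r": res.r, "p_value": res.p_value, "n": res.n}
        with open(outdir / "correlations.json", "w") as fh:
            json.dump(correlations, fh, indent=2, sort_keys=True)

    quartiles = None
    if enrich is not None and len(all_steps) >= 8:
        qt = periodicity_stats.quartile_analysis(
            all_steps, symmetric["cpd_enrichment"])
        quartiles = qt
        with open(outdir / "quartile_table.json", "w") as fh:
            json.dump({
                "thresholds": qt.thresholds,
                "group_means": qt.group_means(),
                "group_n": {k: int(len(v)) for k, v in qt.categories.items()},
                "anova_f": qt.anova_f, "anova_p": qt.anova_p,
                "tukey": {f"{a}|{b}": p for (a, b), p in qt.tukey.items()},
            }, fh, indent=2, sort_keys=True)

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "counts": counts,
        "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()
                          and p.name != "manifest.json"),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "records": records,
        "steps": all_steps,
        "profiles": aggregated,
        "symmetrized": symmetric,
        "enrichment": enrich,
        "periodograms": periodograms,
        "correlations": correlations,
        "quartiles": quartiles,
        "manifest": manifest,
    }
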