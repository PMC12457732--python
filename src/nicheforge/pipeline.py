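"""End-to-end per-species workflow.

clean -> select variables -> replicate fitting -> AUC/TSS filtering ->
TSS^2-weighted consensus -> LPT binarization -> change and area accounting ->
uncertainty maps -> timber valuation. Every stage is a pure function of the
configuration and master seed; per-species child seeds are derived by hashing
the species name into a SeedSequence, so adding a species never perturbs
another's results.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, io
from .change import (BinaryRangeRaster, ChangeSummary, binarize,
                     lowest_presence_threshold, summarize_change, change_map)
from .economics import TimberParams, economic_change_table
from .ensemble import ConsensusRaster, EnsembleError, per_gcm_consensus, range_normalize, weighted_consensus
from .env_stack import spearman_select
from .grid import Raster, RasterStack
from .models import ALGORITHMS, predict_raster
from .occurrences import clean_occurrences, rasterize_presences
from .replicates import FittedReplicate, fit_replicates, make_replicates
from .uncertainty import sd_map

PRESENT = "present"


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``stacks`` maps a period label to the stacks of that period — one per
    climate source (GCM); the "present" period must be present and have
    exactly one stack. Thresholds default to the standard protocol:
    Spearman 0.6, 100 repetitions, 70/30 split, 1:1 pseudoabsences,
    AUC >= 0.75 and TSS >= 0.7.
    """

    occurrences: pd.DataFrame
    stacks: dict[str, list[RasterStack]]
    species: list[str] | None = None
    spearman_threshold: float = 0.6
    selection_groups: list[list[str]] | None = None
    variable_priority: list[str] | None = None
    n_reps: int = 100
    train_frac: float = 0.7
    pa_ratio: float = 1.0
    auc_min: float = 0.75
    tss_min: float = 0.7
    algorithms: tuple[str, ...] = ALGORITHMS
    rf_trees: int = 500
    timber: TimberParams = dc_field(default_factory=TimberParams)
    seed: int = 0
    outdir: str | Path | None = None

    def __post_init__(self) -> None:
        if PRESENT not in self.stacks:
            raise ValueError('stacks must include a "present" period')
        if len(self.stacks[PRESENT]) != 1:
            raise ValueError("the present period must have exactly one stack")
        if not (0 < self.train_frac < 1):
            raise ValueError("train_frac must be in (0, 1)")
        if self.pa_ratio != 1.0:
            raise ValueError("only 1:1 presence:pseudoabsence is supported")
        for t in (self.auc_min,):
            if not 0 <= t <= 1:
                raise ValueError("auc_min must be in [0, 1]")
        if not -1 <= self.tss_min <= 1:
            raise ValueError("tss_min must be in [-1, 1]")


@dataclass
class SpeciesResult:
    """All per-species artifacts of one run."""

    species: str
    n_presence_cells: int
    replicates: list[FittedReplicate]
    retained: list[FittedReplicate]
    retention: dict[str, tuple[int, int]]
    consensus: dict[str, ConsensusRaster]            # period -> pooled consensus
    gcm_consensus: dict[str, dict[str, ConsensusRaster]]  # period -> gcm -> consensus
    lpt: float
    binary: dict[str, BinaryRangeRaster]             # period -> binary range
    change_maps: dict[str, Raster]                   # scenario period -> categorical map
    change_summaries: list[ChangeSummary]
    uncertainty_gcm: dict[str, Raster]               # period -> across-GCM SD
    uncertainty_algorithm: dict[str, Raster]         # period -> across-algorithm SD
    seed: int


@dataclass
class RunResult:
    config: RunConfig
    selected_variables: list[str]
    clean_report: dict
    species_results: dict[str, SpeciesResult]
    failed_species: dict[str, str]
    economics: dict[str, dict]                       # scenario period -> totals
    economics_tables: dict[str, pd.DataFrame]
    manifest: dict


def species_seed(master: int, species: str) -> int:
    ss = np.random.SeedSequence([master, zlib.crc32(species.encode("utf-8"))])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _normalized_members(retained: list[FittedReplicate],
                        stack: RasterStack, var_names: list[str]) -> list[tuple[Raster, float, str, str]]:
    """Project retained models onto a stack; (normalized raster, tss, gcm, algorithm)."""
    members = []
    for rep in retained:
        raster = predict_raster(rep.model, stack, var_names)
        try:
            raster = range_normalize(raster)
        except EnsembleError:
            warnings.warn(
                f"replicate {rep.spec.algorithm}#{rep.spec.rep_index} projects to a "
                f"constant raster on {stack.period_label}/{stack.source_model_label}; skipped",
                stacklevel=2)
            continue
        members.append((raster, rep.tss, stack.source_model_label, rep.spec.algorithm))
    return members


def _algorithm_consensus(members: list[tuple[Raster, float, str, str]],
                         species: str, period: str) -> dict[str, ConsensusRaster]:
    by_alg: dict[str, list[tuple[Raster, float]]] = {}
    for raster, tss, _gcm, alg in members:
        by_alg.setdefault(alg, []).append((raster, tss))
    return {alg: weighted_consensus(group, species=species, period_label=period)
            for alg, group in by_alg.items()}


def _run_species(config: RunConfig, species: str, table: pd.DataFrame,
                 present_stack: RasterStack, var_names: list[str]) -> SpeciesResult:
    seed = species_seed(config.seed, species)
    sub = table[table["species"] == species]
    presence = rasterize_presences(sub, present_stack.grid)
    pool = np.setdiff1d(present_stack.valid_flat_indices, presence.cells)

    specs = make_replicates(presence, pool, n_reps=config.n_reps,
                            train_frac=config.train_frac,
                            algorithms=config.algorithms, seed=seed)
    fitted = fit_replicates(specs, present_stack, var_names, rf_trees=config.rf_trees)
    retained = evaluation.filter_replicates(fitted, config.auc_min, config.tss_min)
    retention = evaluation.retention_by_algorithm(fitted, retained)

    # present-day consensus from the replicates' own (normalized) predictions
    present_members = [(range_normalize(r.prediction), r.tss, r.source_model_label,
                        r.spec.algorithm) for r in retained]
    consensus: dict[str, ConsensusRaster] = {
        PRESENT: weighted_consensus([(m[0], m[1]) for m in present_members],
                                    species=species, period_label=PRESENT)
    }
    gcm_consensus: dict[str, dict[str, ConsensusRaster]] = {}
    uncertainty_alg: dict[str, Raster] = {}
    uncertainty_gcm: dict[str, Raster] = {}

    alg_cons = _algorithm_consensus(present_members, species, PRESENT)
    if len(alg_cons) >= 2:
        u = sd_map([c.as_raster() for c in alg_cons.values()], list(alg_cons))
        uncertainty_alg[PRESENT] = Raster(u.grid, u.values)

    lpt = lowest_presence_threshold(consensus[PRESENT], presence)
    binary: dict[str, BinaryRangeRaster] = {PRESENT: binarize(consensus[PRESENT], lpt)}
    change_maps: dict[str, Raster] = {}
    summaries: list[ChangeSummary] = []

    for period, period_stacks in config.stacks.items():
        if period == PRESENT:
            continue
        members: list[tuple[Raster, float, str, str]] = []
        for stack in period_stacks:
            members.extend(_normalized_members(retained, stack.subset(var_names), var_names))
        if not members:
            raise RuntimeError(f"no usable ensemble members for period {period!r}")
        consensus[period] = weighted_consensus([(m[0], m[1]) for m in members],
                                               species=species, period_label=period)
        gcm_consensus[period] = per_gcm_consensus([(m[0], m[1], m[2]) for m in members],
                                                  species=species, period_label=period)
        if len(gcm_consensus[period]) >= 2:
            u = sd_map([c.as_raster() for c in gcm_consensus[period].values()],
                       list(gcm_consensus[period]))
            uncertainty_gcm[period] = Raster(u.grid, u.values)
        alg_cons = _algorithm_consensus(members, species, period)
        if len(alg_cons) >= 2:
            u = sd_map([c.as_raster() for c in alg_cons.values()], list(alg_cons))
            uncertainty_alg[period] = Raster(u.grid, u.values)

        binary[period] = binarize(consensus[period], lpt)
        change_maps[period] = change_map(binary[PRESENT], binary[period])
        summaries.append(summarize_change(species, binary[PRESENT], binary[period], period))

    return SpeciesResult(
        species=species, n_presence_cells=len(presence), replicates=fitted,
        retained=retained, retention=retention, consensus=consensus,
        gcm_consensus=gcm_consensus, lpt=lpt, binary=binary,
        change_maps=change_maps, change_summaries=summaries,
        uncertainty_gcm=uncertainty_gcm, uncertainty_algorithm=uncertainty_alg,
        seed=seed)


def metrics_table(result: SpeciesResult, auc_min: float, tss_min: float) -> pd.DataFrame:
    """Replicate evaluation metrics, one row per algorithm x repetition."""
    rows = [{
        "species": result.species,
        "algorithm": r.spec.algorithm,
        "rep": r.spec.rep_index,
        "auc": r.auc,
        "tss": r.tss,
        "threshold": r.threshold,
        "retained": bool(r.auc >= auc_min and r.tss >= tss_min),
        "seed": r.spec.seed,
    } for r in result.replicates]
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full workflow for every species in the configuration.

    A species whose pipeline fails (too few presence cells, no replicate
    passing the filter, ...) is recorded in ``failed_species`` and the run
    continues with the others.
    """
    table, report = clean_occurrences(config.occurrences)
    present_stack = config.stacks[PRESENT][0]

    if config.selection_groups:
        selected: list[str] = []
        for group in config.selection_groups:
            prio = [v for v in (config.variable_priority or group) if v in group]
            selected.extend(spearman_select(present_stack.subset(group),
                                            config.spearman_threshold, priority=prio))
    else:
        selected = spearman_select(present_stack, config.spearman_threshold,
                                   priority=config.variable_priority)

    species_list = config.species or sorted(table["species"].unique())
    results: dict[str, SpeciesResult] = {}
    failures: dict[str, str] = {}
    for sp in species_list:
        try:
            results[sp] = _run_species(config, sp, table, present_stack.subset(selected),
                                       selected)
        except Exception as exc:  # noqa: BLE001 — isolate per-species failures
            warnings.warn(f"species {sp!r} failed: {exc}", stacklevel=2)
            failures[sp] = str(exc)

    economics: dict[str, dict] = {}
    economics_tables: dict[str, pd.DataFrame] = {}
    periods = [p for p in config.stacks if p != PRESENT]
    for period in periods:
        summaries = [s for r in results.values() for s in r.change_summaries
                     if s.period_label == period]
        if summaries:
            tbl, totals = economic_change_table(summaries, config.timber)
            economics[period] = totals
            economics_tables[period] = tbl

    manifest = {
        "seed": config.seed,
        "selected_variables": selected,
        "clean_report": report.as_dict(),
        "parameters": {
            "spearman_threshold": config.spearman_threshold,
            "n_reps": config.n_reps,
            "train_frac": config.train_frac,
            "pa_ratio": config.pa_ratio,
            "auc_min": config.auc_min,
            "tss_min": config.tss_min,
            "algorithms": list(config.algorithms),
            "rf_trees": config.rf_trees,
            "timber": {"volume_density": config.timber.volume_density,
                       "price": config.timber.price},
        },
        "species": {
            sp: {
                "seed": r.seed,
                "n_presence_cells": r.n_presence_cells,
                "n_candidate_replicates": len(r.replicates),
                "n_retained": len(r.retained),
                "retention_by_algorithm": {k: list(v) for k, v in r.retention.items()},
                "lpt": r.lpt,
                "change": [s.as_dict() for s in r.change_summaries],
            } for sp, r in results.items()
        },
        "failed_species": failures,
        "economics": economics,
    }

    run = RunResult(config=config, selected_variables=selected,
                    clean_report=report.as_dict(), species_results=results,
                    failed_species=failures, economics=economics,
                    economics_tables=economics_tables, manifest=manifest)
    if config.outdir is not None:
        _write_artifacts(run, Path(config.outdir))
    return run


def _write_artifacts(run: RunResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_json(outdir / "manifest.json", run.manifest)
    cfg = run.config
    for sp, res in run.species_results.items():
        spdir = outdir / sp.replace(" ", "_")
        spdir.mkdir(exist_ok=True)
        metrics_table(res, cfg.auc_min, cfg.tss_min).to_csv(spdir / "metrics.csv", index=False)
        for period, cons in res.consensus.items():
            io.write_ascii_grid(spdir / f"consensus_{period}.asc", cons.as_raster())
        for period, b in res.binary.items():
            io.write_ascii_grid(spdir / f"binary_{period}.asc", Raster(b.grid, b.values))
        for period, cmap in res.change_maps.items():
            io.write_ascii_grid(spdir / f"change_{period}.asc", cmap)
        for period, u in res.uncertainty_gcm.items():
            io.write_ascii_grid(spdir / f"sd_gcm_{period}.asc", u)
        for period, u in res.uncertainty_algorithm.items():
            io.write_ascii_grid(spdir / f"sd_algorithm_{period}.asc", u)
        if res.change_summaries:
            pd.DataFrame([s.as_dict() for s in res.change_summaries]).to_csv(
                spdir / "change_summary.csv", index=False)
    for period, tbl in run.economics_tables.items():
        tbl.to_csv(outdir / f"economics_{period.replace(' ', '_')}.csv", index=False)
    if run.economics:
        io.write_json(outdir / "economics_totals.json", run.economics)
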