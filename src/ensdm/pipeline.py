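"""End-to-end pipeline: simulate -> prepare -> screen -> fit -> evaluate ->
predict -> classify -> change accounting.

Every stochastic stage draws its seed from one master seed, so a rerun with
the same config reproduces every number; the run directory receives all
rasters and tables plus a JSON manifest with a checksum per output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ensemble import (
    EnsembleModel,
    ImportanceTable,
    build_ensemble,
    ensemble_predict_raster,
    variable_importance,
)
from .evaluation import EvaluationResult, evaluate_records, performance_table
from .geodata_io import (
    OccurrenceSet,
    PredictorStack,
    RasterGrid,
    write_occurrences,
    write_raster,
)
from .models import AlgorithmSpec, cross_validate, fit_model
from .occurrences import SamplingConfig, deduplicate, generate_pseudo_absences
from .predictors import extract_features, screen_predictors
from .suitability_change import (
    AreaSummary,
    ChangeMap,
    ClassificationScheme,
    area_summary,
    change_map,
    change_rate_result,
    classify,
    scenario_report,
)
from .synthetic_data import (
    ScenarioShift,
    WorldConfig,
    apply_shift,
    default_species,
    make_climate_stack,
    sample_presences,
    true_suitability,
)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "default_scenarios"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved configuration of one full synthetic-world run."""

    seed: int = 0
    world: dict = field(default_factory=dict)  # WorldConfig overrides
    n_presences: int = 400
    n_pseudo_absences: int = 800
    min_distance_km: float = 5.0
    r_threshold: float = 0.7
    vif_threshold: float = 10.0
    algorithms: tuple[str, ...] = ("MARS", "BRT", "MLP", "RF", "SVM")
    cv_k: int = 4
    cv_runs: int = 10
    cv_scheme: str = "kfold"
    weighting_metric: str = "AUC"
    importance_repeats: int = 5
    suitable_floor: str = "low"
    scenarios: dict[str, dict[str, float]] | None = None  # "period:tag" -> deltas

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "algorithms" in data:
            data["algorithms"] = tuple(data["algorithms"])
        return cls(**data)


def default_scenarios() -> dict[str, dict[str, float]]:
    """Additive shifts standing in for two periods x two forcing levels."""
    return {
        "2050:low-forcing": {"signal1": 0.3},
        "2050:high-forcing": {"signal1": 0.8, "signal2": 0.3},
        "2070:low-forcing": {"signal1": 0.5},
        "2070:high-forcing": {"signal1": 1.2, "signal2": 0.5},
    }


@dataclass
class PipelineResult:
    """Everything one run produced, in memory."""

    config: RunConfig
    stack: PredictorStack
    truth: RasterGrid
    occurrences: OccurrenceSet
    screen_report: Any
    cv_records: list
    evaluations: list[EvaluationResult]
    performance: pd.DataFrame
    ensemble: EnsembleModel
    importance: ImportanceTable
    current_suitability: RasterGrid
    scenario_suitability: dict[tuple[str, str], RasterGrid]
    current_summary: AreaSummary
    scenario_summaries: dict[tuple[str, str], AreaSummary]
    change_maps: dict[tuple[str, str], ChangeMap]
    areas_table: pd.DataFrame
    rates_table: pd.DataFrame
    manifest: dict


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _parse_tag(key: str) -> tuple[str, str]:
    period, _, label = key.partition(":")
    return period, label


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Execute the full analysis on the synthetic world.

    If ``outdir`` is given, all rasters/tables and a manifest are written
    there; otherwise the run stays in memory.
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s % (2**31 - 1)) for s in ss.generate_state(6)]
    world_seed, presence_seed, absence_seed, cv_seed, algo_seed, imp_seed = seeds

    # --- simulate -----------------------------------------------------------
    world = WorldConfig(seed=world_seed, **config.world)
    stack = make_climate_stack(world)
    species = default_species(world)
    truth = true_suitability(species, stack)
    logger.info("simulate: %dx%d grid, %d layers", *stack.shape, len(stack))

    # --- prepare ------------------------------------------------------------
    presences = sample_presences(truth, config.n_presences, seed=presence_seed)
    presences = deduplicate(presences, stack)
    sampling = SamplingConfig(
        n_pseudo_absence=config.n_pseudo_absences,
        min_distance_km=config.min_distance_km,
        seed=absence_seed,
    )
    absences = generate_pseudo_absences(presences, stack, sampling)
    occurrences = presences.concat(absences)
    logger.info("prepare: %d presences + %d pseudo-absences", len(presences), len(absences))

    # --- screen -------------------------------------------------------------
    table = extract_features(stack, occurrences)
    report = screen_predictors(
        table, r_threshold=config.r_threshold, vif_threshold=config.vif_threshold
    )
    screened = table.subset(report.retained)
    logger.info("screen: retained %s", ", ".join(report.retained))

    # --- evaluate (cross-validation) ---------------------------------------
    specs = [
        AlgorithmSpec(aid, seed=algo_seed + i) for i, aid in enumerate(config.algorithms)
    ]
    records = cross_validate(
        screened, specs, k=config.cv_k, runs=config.cv_runs,
        seed=cv_seed, scheme=config.cv_scheme,
    )
    evaluations = evaluate_records(records)
    perf = performance_table(evaluations)

    # --- fit final members + ensemble --------------------------------------
    members = [fit_model(spec, screened) for spec in specs]
    ens = build_ensemble(members, evaluations, metric=config.weighting_metric)
    importance = variable_importance(
        ens, screened, repeats=config.importance_repeats, seed=imp_seed
    )

    # --- predict + classify -------------------------------------------------
    scheme = ClassificationScheme()
    current = ensemble_predict_raster(ens, stack)
    current_cls = classify(current, scheme)
    current_summary = area_summary(current_cls, ("current", ""), scheme)

    scenarios = config.scenarios if config.scenarios is not None else default_scenarios()
    scenario_suit: dict[tuple[str, str], RasterGrid] = {}
    scenario_summaries: dict[tuple[str, str], AreaSummary] = {}
    change_maps_out: dict[tuple[str, str], ChangeMap] = {}
    for key, deltas in scenarios.items():
        tag = _parse_tag(key)
        # a collinear duplicate is the same physical variable: shift it too
        full_deltas = dict(deltas)
        for name, prov in stack.provenance.items():
            for parent, delta in deltas.items():
                if prov == f"collinear copy of {parent}":
                    full_deltas[name] = delta
        shifted = apply_shift(stack, ScenarioShift(deltas=full_deltas, tag=tag))
        suit = ensemble_predict_raster(ens, shifted)
        cls = classify(suit, scheme)
        scenario_suit[tag] = suit
        scenario_summaries[tag] = area_summary(cls, tag, scheme)
        change_maps_out[tag] = change_map(
            current_cls, cls, suitable_floor=config.suitable_floor, scheme=scheme
        )
    areas, rates = scenario_report(current_summary, scenario_summaries, scheme)

    # --- persist ------------------------------------------------------------
    manifest: dict = {
        "package_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "stage_seeds": dict(
            zip(["world", "presence", "absence", "cv", "algorithms", "importance"], seeds)
        ),
        "n_presences": len(presences),
        "n_pseudo_absences": len(absences),
        "retained_predictors": report.retained,
        "weights": {
            m.spec.algorithm_id: float(w) for m, w in zip(ens.members, ens.weights)
        },
        "outputs": {},
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(outdir / "config.yaml")
        write_raster(truth, outdir / "truth.tif")
        write_occurrences(occurrences, outdir / "occurrences.csv")
        write_raster(current, outdir / "suitability_current.tif")
        write_raster(current_cls, outdir / "classes_current.tif")
        for (period, label), suit in scenario_suit.items():
            write_raster(suit, outdir / f"suitability_{period}_{label}.tif")
        for (period, label), cm in change_maps_out.items():
            write_raster(cm.raster, outdir / f"change_{period}_{label}.tif")
        perf.to_csv(outdir / "performance.csv")
        importance.to_frame().to_csv(outdir / "importance.csv")
        areas.to_csv(outdir / "areas.csv")
        rates.to_csv(outdir / "change_rates.csv")
        (outdir / "screen_report.json").write_text(json.dumps(report.to_dict(), indent=2))
        for f in sorted(outdir.iterdir()):
            if f.name != "manifest.json":
                manifest["outputs"][f.name] = _checksum(f)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return PipelineResult(
        config=config,
        stack=stack,
        truth=truth,
        occurrences=occurrences,
        screen_report=report,
        cv_records=records,
        evaluations=evaluations,
        performance=perf,
        ensemble=ens,
        importance=importance,
        current_suitability=current,
        scenario_suitability=scenario_suit,
        current_summary=current_summary,
        scenario_summaries=scenario_summaries,
        change_maps=change_maps_out,
        areas_table=areas,
        rates_table=rates,
        manifest=manifest,
    )
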