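"""End-to-end runs: movie pipeline and expression pipeline.

Each run takes a :class:`~emtconv.config.RunConfig`, executes every
stage (detect → classify → link → lineages → kinetics, or normalize →
merge → score → stratify), writes all intermediate tables with the
config hash and seed in a header comment, and returns a machine-
readable summary. Identical config + seed give identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Optional, Sequence

import numpy as np
import pandas as pd

from . import io, kinetics, meta, morphology, scoring, tracking
from .config import RunConfig
from .synthetic import movie as synmovie
from .synthetic import compendium as syncomp

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {detail}")


def movie_config_from_dict(d: Optional[dict[str, Any]], seed: int) -> synmovie.MovieConfig:
    cfg = synmovie.MovieConfig(seed=seed)
    if not d:
        return cfg
    d = dict(d)
    if "conversion_schedule" in d:
        d["conversion_schedule"] = [
            synmovie.ConversionRule(
                fraction=r["fraction"], mode=r["mode"],
                frame_window=tuple(r["frame_window"]),
                target=r.get("target", morphology.NEURON_LIKE),
            )
            for r in d["conversion_schedule"]
        ]
    if "shape_params" in d:
        d["shape_params"] = {
            k: synmovie.ArchetypeShape(**v) for k, v in d["shape_params"].items()
        }
    if "field_size" in d:
        d["field_size"] = tuple(d["field_size"])
    known = {f.name for f in dataclasses.fields(synmovie.MovieConfig)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown movie config keys: {sorted(unknown)}")
    for k, v in d.items():
        setattr(cfg, k, v)
    cfg.seed = seed
    return cfg


@dataclass
class MovieResult:
    observations: list[list[morphology.CellObservation]]
    links: list[tracking.FrameLink]
    forest: tracking.LineageForest
    time_course: pd.DataFrame
    growth: pd.DataFrame
    conversions: list[kinetics.ConversionEvent]
    mode_summary: pd.DataFrame
    migration: pd.DataFrame
    summary: dict[str, Any]


def analyze_movie(
    labels: np.ndarray,
    nuclei: Optional[np.ndarray],
    config: RunConfig,
    truth: Optional[synmovie.SyntheticTruth] = None,
    motion_step_sd: Optional[float] = None,
) -> MovieResult:
    """Run detection, classification, tracking and kinetics on a label
    stack. When generator truth is supplied, marker overlap and lineage
    accuracy are added to the summary."""
    thresholds = morphology.ClassThresholds(**config.thresholds)
    n_frames = labels.shape[0]

    try:
        observations = []
        for t in range(n_frames):
            nuc = nuclei[t] if nuclei is not None else None
            obs = morphology.detect_cells(
                labels[t], nuc, frame=t, min_neurite_len=thresholds.min_neurite_len
            )
            morphology.classify_frame(obs, thresholds)
            observations.append(obs)
    except Exception as e:  # noqa: BLE001 - stage boundary
        raise StageError("detect/classify", str(e)) from e

    gate = config.tracking.get("gate")
    if gate is None:
        # default: 5× the motion step SD when the generator config is
        # known, else 50 px
        gate = 5.0 * motion_step_sd if motion_step_sd else 50.0
        logger.info("tracking gate defaulted to %.1f px", gate)
    division_radius = config.tracking.get("division_radius")

    try:
        links = [
            tracking.link_frames(observations[t], observations[t + 1], gate,
                                 division_radius)
            for t in range(n_frames - 1)
        ]
        forest = tracking.build_lineages(links, observations)
    except Exception as e:  # noqa: BLE001
        raise StageError("tracking", str(e)) from e

    kin = config.kinetics
    frames_per_day = kin.get("frames_per_day", 24)
    persistence = kin.get("persistence", 3)
    mitosis_threshold = kin.get("mitosis_threshold", 1)
    recent_window = kin.get("recent_window", 24)

    try:
        time_course = kinetics.class_time_course(forest, n_frames, frames_per_day)
        counts = [len(o) for o in observations]
        growth = kinetics.growth_table(counts, frames_per_day)
        conversions = kinetics.detect_conversions(
            forest, n_frames, persistence=persistence,
            mitosis_threshold=mitosis_threshold, recent_window=recent_window,
        )
        mode_summary = kinetics.mitosis_contribution_summary(
            conversions, forest, n_frames
        )
    except Exception as e:  # noqa: BLE001
        raise StageError("kinetics", str(e)) from e

    migration_rows = []
    for t in range(n_frames - 1):
        for o in observations[t]:
            rec = tracking.migration_distance(
                observations[t], observations[t + 1], links[t], o.label
            )
            if rec is not None:
                migration_rows.append((rec.cell, rec.frame, rec.distance, rec.imputed))
    migration = pd.DataFrame(
        migration_rows, columns=["cell", "frame", "distance", "imputed"]
    )

    final_obs = observations[-1]
    predicted_neuron = {
        o.label for o in final_obs if o.assigned_class == morphology.NEURON_LIKE
    }
    n_final = len(final_obs)
    n_classified = sum(
        o.assigned_class != morphology.UNCLASSIFIED for o in final_obs
    )
    summary: dict[str, Any] = {
        "n_frames": int(n_frames),
        "n_final_cells": int(n_final),
        "final_class_counts": {
            c: int(sum(o.assigned_class == c for o in final_obs))
            for c in morphology.CLASSES
        },
        "pct_classified_final": 100.0 * n_classified / n_final if n_final else None,
        "n_links": int(sum(len(l.links) for l in links)),
        "n_divisions": int(sum(len(l.divisions) for l in links)),
        "n_conversion_events": len(conversions),
        "mode_summary": mode_summary.to_dict(orient="records"),
        "mean_migration_px_per_h": float(migration.distance.mean())
        if len(migration) else None,
        "gate_px": float(gate),
    }

    if truth is not None:
        overlap = morphology.marker_overlap(predicted_neuron, truth.marker_positive)
        summary["marker_overlap_jaccard_pct"] = overlap.jaccard
        summary["marker_overlap_recall_pct"] = overlap.recall
        summary["marker_overlap_vacuous"] = overlap.vacuous
        # lineage accuracy: identity links that connect the same true cell
        truth_pairs = 0
        correct = 0
        tc = truth.cells
        for t in range(n_frames - 1):
            now = set(tc.loc[tc.frame == t, "cell_id"])
            nxt = set(tc.loc[tc.frame == t + 1, "cell_id"])
            truth_pairs += len(now & nxt)
            correct += sum(1 for a, b in links[t].links if a == b and a in now)
        summary["link_accuracy_pct"] = 100.0 * correct / truth_pairs if truth_pairs else None

    return MovieResult(observations, links, forest, time_course, growth,
                       conversions, mode_summary, migration, summary)


def run_movie_pipeline(config: RunConfig, outdir: str | Path) -> dict[str, Any]:
    """Simulate (or load) a movie, analyze it, and write every table."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = config.header()

    truth = None
    motion_sd = None
    if config.movie is not None:
        mcfg = movie_config_from_dict(config.movie, config.seed)
        labels, nuclei, truth = synmovie.generate_movie(mcfg)
        motion_sd = max(mcfg.motion_step_sd.values())
        io.write_label_stack(labels, outdir / "movie_labels.tif")
        io.write_label_stack(nuclei, outdir / "movie_nuclei.tif")
        io.write_table(truth.cells, outdir / "truth_cells.tsv", header)
        io.write_table(truth.conversions, outdir / "truth_conversions.tsv", header)
        io.write_table(truth.divisions, outdir / "truth_divisions.tsv", header)
    else:
        movie_path = config.paths.get("movie")
        if not movie_path or not Path(movie_path).exists():
            raise FileNotFoundError(f"input movie not found: {movie_path!r}")
        labels = io.read_label_stack(movie_path)
        nuclei_path = config.paths.get("nuclei")
        nuclei = io.read_label_stack(nuclei_path) if nuclei_path else None

    result = analyze_movie(labels, nuclei, config, truth, motion_sd)

    io.write_table(io.observations_to_table(result.observations),
                   outdir / "observations.tsv", header)
    io.write_table(result.time_course, outdir / "class_time_course.tsv", header)
    io.write_table(result.growth, outdir / "growth.tsv", header)
    io.write_table(result.migration, outdir / "migration.tsv", header)
    io.write_table(result.mode_summary, outdir / "mode_summary.tsv", header)
    lineage_rows = [
        (n.node_id, n.parent, n.first_frame, n.last_frame, n.end_reason)
        for n in result.forest.nodes.values()
    ]
    io.write_table(
        pd.DataFrame(lineage_rows,
                     columns=["node", "parent", "first_frame", "last_frame",
                              "end_reason"]),
        outdir / "lineage.tsv", header,
    )
    summary = {"config_hash": config.config_hash(), "seed": config.seed,
               **result.summary}
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def run_expression_pipeline(config: RunConfig, outdir: str | Path) -> dict[str, Any]:
    """Simulate (or load) an expression compendium, run the
    meta-analysis and score report."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = config.header()

    if config.compendium is not None:
        ccfg = syncomp.CompendiumConfig(**{**config.compendium, "seed": config.seed})
        datasets, truth = syncomp.generate_compendium(ccfg)
        io.write_table(truth, outdir / "truth_compendium.tsv", header)
    else:
        raise FileNotFoundError(
            "expression pipeline needs synthetic compendium settings "
            "(loading external dataset TSVs: use emtconv.io.expression_from_tsv)"
        )

    try:
        normalized = {d.dataset_id: meta.normalize_dataset(d) for d in datasets}
        comp = meta.merge_by_symbol(normalized, species="mouse")
    except Exception as e:  # noqa: BLE001
        raise StageError("normalize/merge", str(e)) from e

    signature = scoring.SignatureSet(
        "EMT", up=tuple(ccfg.up_genes), down=tuple(ccfg.down_genes)
    )
    scores = meta.score_columns(comp, signature)
    fold = config.meta.get("fold_threshold", 1.5)
    quant = config.meta.get("strong_quantile", 0.25)
    stat3 = meta.upregulation_fraction(comp, "Stat3", fold)
    strat = meta.stratify_by_emt(comp, signature, strong_quantile=quant,
                                 fold_threshold=fold)

    flat = comp.matrix.copy()
    flat.columns = [f"{a}:{b}" for a, b in flat.columns]
    io.write_table(flat.rename_axis("gene").reset_index(),
                   outdir / "merged_compendium.tsv", header)
    io.write_table(strat, outdir / "stratification.tsv", header)
    score_df = pd.DataFrame({
        "column": [f"{a}:{b}" for a, b in scores.index],
        "emt_score": scores.values,
    })
    io.write_table(score_df, outdir / "emt_scores.tsv", header)

    summary = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_datasets": len(datasets),
        "n_columns": comp.n_columns,
        "stat3_upregulation_pct": stat3.percent,
        "stat3_basis": stat3.basis,
        "fold_threshold": fold,
        "strong_quantile": quant,
        "stratification": strat.to_dict(orient="records"),
        "mean_emt_score": float(scores.mean()),
    }
    (outdir / "report.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
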