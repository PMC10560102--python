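"""End-to-end orchestration: curate -> featurize -> select -> train -> predict.

One TOML config drives all stages; every parameter has a default mirroring
the published protocol (Tanimoto cutoff 0.85, Pearson-threshold sweep
0.1-0.9 with 10-fold cross-validation, LightGBM, permeability cutoff -1).
A run writes its artifacts (curated dataset, feature table, model archive,
evaluation report, optional predictions) plus a manifest recording input
hashes, all effective parameters and stage timings; reruns with identical
inputs and seeds produce identical outputs.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__
from .chem_io import read_dataset, write_dataset, write_predictions
from .errors import ConfigError, LogBBError
from .evaluation import binarize
from .feature_selection import correlation_filter, sweep_thresholds
from .featurization import DescriptorTable, compute_descriptors, prune_missing
from .modeling import (
    LearnerSpec,
    cross_validate,
    grid_search,
    load_grids,
    predict,
    save_model,
    train,
)
from .similarity import deduplicate

logger = logging.getLogger(__name__)

DEFAULTS: dict[str, dict[str, Any]] = {
    "input": {"dataset": None, "query": None},
    "curation": {"tanimoto_cutoff": 0.85},
    "featurization": {"include_3d": False, "conformer_seed": 42},
    "selection": {"threshold": None, "thresholds": [round(0.1 * i, 1) for i in range(1, 10)]},
    "model": {
        "learner": "lightgbm",
        "params": {},
        "grid": None,  # path to a TOML grid file enables grid search
        "folds": 10,
        "seed": 42,
        "prescale": False,
    },
    "evaluation": {"cutoff": -1.0},
    "output": {"dir": "logbb_run"},
}


class StageError(LogBBError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunManifest:
    tool_version: str
    input_hashes: dict[str, str]
    parameters: dict[str, Any]
    stage_timings: dict[str, float] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    stage_counts: dict[str, Any] = field(default_factory=dict)


def _merge_config(user: dict[str, Any]) -> dict[str, Any]:
    cfg = {section: dict(values) for section, values in DEFAULTS.items()}
    for section, values in user.items():
        if section not in cfg:
            raise ConfigError(f"unknown config section {section!r}")
        if not isinstance(values, dict):
            raise ConfigError(f"section {section!r} must be a table")
        for key, val in values.items():
            if key not in cfg[section]:
                raise ConfigError(f"unknown key {section}.{key}")
            cfg[section][key] = val
    return cfg


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path, "rb") as fh:
        return _merge_config(tomllib.load(fh))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: str | Path | dict[str, Any], out_dir: str | Path | None = None) -> dict:
    """Execute the full workflow from a config file or dict; returns artifact paths.

    Stages run in order: curate, featurize, select, train, evaluate,
    predict (if a query file is configured). Any stage failure aborts with
    the failing stage named in the raised :class:`StageError`.
    """
    if isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = _merge_config(config)
    if not cfg["input"]["dataset"]:
        raise ConfigError("input.dataset is required")

    out = Path(out_dir or cfg["output"]["dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["model"]["seed"])
    manifest = RunManifest(
        tool_version=__version__,
        input_hashes={},
        parameters=cfg,
    )
    dataset_path = Path(cfg["input"]["dataset"])
    manifest.input_hashes[str(dataset_path)] = _sha256(dataset_path)
    if cfg["input"]["query"]:
        manifest.input_hashes[str(cfg["input"]["query"])] = _sha256(Path(cfg["input"]["query"]))

    artifacts: dict[str, Any] = {"out_dir": out}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except LogBBError:
                raise
            except Exception as exc:  # propagate with stage context
                raise StageError(name, exc) from exc
            manifest.stage_timings[name] = round(time.perf_counter() - t0, 4)
            return result

        return deco

    # --- curate -----------------------------------------------------------
    @stage("curate")
    def _curate():
        records = read_dataset(dataset_path)
        kept, decisions = deduplicate(records, cutoff=float(cfg["curation"]["tanimoto_cutoff"]))
        logger.info("curate: %d -> %d compounds (%d discarded)", len(records), len(kept), len(decisions))
        manifest.stage_counts["compounds_in"] = len(records)
        manifest.stage_counts["compounds_kept"] = len(kept)
        path = out / "curated.csv"
        write_dataset(kept, path)
        manifest.outputs.append(str(path))
        return kept

    kept = _curate

    # --- featurize --------------------------------------------------------
    @stage("featurize")
    def _featurize():
        table = compute_descriptors(
            kept,
            include_3d=bool(cfg["featurization"]["include_3d"]),
            conformer_seed=int(cfg["featurization"]["conformer_seed"]),
        )
        pruned = prune_missing(table)
        manifest.stage_counts["descriptors_computed"] = table.shape[1]
        manifest.stage_counts["descriptors_after_pruning"] = pruned.shape[1]
        path = out / "features.csv"
        pruned.data.to_csv(path, index_label="id", float_format="%.10g")
        manifest.outputs.append(str(path))
        return pruned

    table = _featurize
    y = np.array([r.logbb for r in kept], dtype=float)
    if not np.isfinite(y).all():
        raise ConfigError("every training compound needs a logBB value")

    learner = LearnerSpec(name=cfg["model"]["learner"])
    folds = int(cfg["model"]["folds"])
    prescale = bool(cfg["model"]["prescale"])

    # --- select -----------------------------------------------------------
    @stage("select")
    def _select():
        fixed = cfg["selection"]["threshold"]
        if fixed is not None:
            # documented shortcut: a fixed threshold skips the sweep
            sel = correlation_filter(table, y, float(fixed))
            chosen_threshold = float(fixed)
        else:
            sweep = sweep_thresholds(
                table,
                y,
                learner,
                thresholds=[float(t) for t in cfg["selection"]["thresholds"]],
                k=folds,
                seed=seed,
                params=dict(cfg["model"]["params"]),
            )
            sel = sweep.chosen_selection
            chosen_threshold = sweep.chosen_threshold
        manifest.stage_counts["pcc_threshold"] = chosen_threshold
        manifest.stage_counts["features_selected"] = len(sel.selected_names)
        logger.info(
            "select: threshold %.2f, %d features", chosen_threshold, len(sel.selected_names)
        )
        return DescriptorTable(data=table.data[sel.selected_names])

    selected = _select

    # --- train ------------------------------------------------------------
    @stage("train")
    def _train():
        grid_path = cfg["model"]["grid"]
        if grid_path:
            grids = load_grids(grid_path)
            spec = LearnerSpec(name=learner.name, param_grid=grids.get(learner.name, {}))
            best_params, model, record = grid_search(
                spec, selected, y, k=folds, seed=seed, prescale=prescale
            )
            manifest.stage_counts["best_params"] = best_params
        else:
            model = train(learner, selected, y, params=dict(cfg["model"]["params"]), seed=seed)
            record = cross_validate(
                learner,
                selected,
                y,
                k=folds,
                seed=seed,
                params=dict(cfg["model"]["params"]),
                prescale=prescale,
            )
        path = out / "model.joblib"
        save_model(model, path)
        manifest.outputs.append(str(path))
        return model, record

    model, cv_record = _train

    # --- evaluate ---------------------------------------------------------
    @stage("evaluate")
    def _evaluate():
        report = {
            "learner": model.learner,
            "n_compounds": len(y),
            "n_features": len(model.feature_names),
            "cv": {
                "k": cv_record.k,
                "seed": cv_record.seed,
                "fold_r2": cv_record.fold_r2,
                "fold_mse": cv_record.fold_mse,
                "mean_r2": cv_record.mean_r2,
                "mean_mse": cv_record.mean_mse,
            },
        }
        path = out / "evaluation.json"
        path.write_text(json.dumps(report, indent=2, sort_keys=True))
        manifest.outputs.append(str(path))
        return report

    report = _evaluate
    artifacts["evaluation"] = report
    artifacts["model"] = model

    # --- predict ----------------------------------------------------------
    if cfg["input"]["query"]:

        @stage("predict")
        def _predict():
            qrecords = read_dataset(Path(cfg["input"]["query"]))
            qtable = compute_descriptors(
                qrecords,
                include_3d=bool(cfg["featurization"]["include_3d"]),
                conformer_seed=int(cfg["featurization"]["conformer_seed"]),
            )
            preds = predict(model, qtable)
            labels = binarize(preds, cutoff=float(cfg["evaluation"]["cutoff"]))
            path = out / "predictions.csv"
            write_predictions(qrecords, preds, labels, path)
            manifest.outputs.append(str(path))
            return path

        artifacts["predictions"] = _predict

    manifest_path = out / "manifest.json"
    manifest_path.write_text(
        json.dumps(
            {
                "tool_version": manifest.tool_version,
                "input_hashes": manifest.input_hashes,
                "parameters": manifest.parameters,
                "stage_counts": manifest.stage_counts,
                "stage_timings": manifest.stage_timings,
                "outputs": manifest.outputs,
            },
            indent=2,
            sort_keys=True,
            default=str,
        )
    )
    artifacts["manifest"] = manifest_path
    return artifacts
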