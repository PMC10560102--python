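"""Learner registry, grid search, and the 10-fold cross-validation harness.

Eight regression learners are exposed under a uniform interface: LightGBM,
random forest (rf), k-nearest neighbours (knn), multiple linear regression
(mlr), support-vector regression (svm), AdaBoost, XGBoost and a single
hidden-layer neural network (ann). All fitting is seeded and single-threaded
so that repeat runs are identical.

Cross-validation uses a shuffled k-fold split from a single integer seed.
By default the feature scaler is refit inside each training fold — the
held-out fold is transformed with training statistics only, which avoids the
mild leakage of scaling the full matrix up front; ``prescale=True`` restores
global pre-scaling for protocol compatibility.
"""
from __future__ import annotations

import itertools
import logging
import tomllib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostRegressor, RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR

from .errors import ModelFormatError, UnknownLearnerError
from .evaluation import mse as _mse
from .evaluation import r_squared as _r2
from .featurization import DescriptorTable, ScalerParams, apply_scaler, fit_scaler

logger = logging.getLogger(__name__)

LEARNER_NAMES = ("lightgbm", "rf", "knn", "mlr", "svm", "adaboost", "xgboost", "ann")
MODEL_FORMAT_VERSION = 1


@dataclass
class LearnerSpec:
    """A named learner plus its hyperparameter search grid."""

    name: str
    param_grid: dict[str, list[Any]] = field(default_factory=dict)
    fixed_params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in LEARNER_NAMES:
            raise UnknownLearnerError(
                f"unknown learner {self.name!r}; expected one of {LEARNER_NAMES}"
            )


@dataclass
class TrainedModel:
    learner: str
    estimator: Any  # fitted scikit-learn-style regressor
    feature_names: list[str]
    scaler: ScalerParams
    metadata: dict[str, Any] = field(default_factory=dict)


@dataclass
class CVRecord:
    k: int
    seed: int
    fold_r2: list[float]
    fold_mse: list[float]
    fold_test_indices: list[np.ndarray]

    @property
    def mean_r2(self) -> float:
        return float(np.mean(self.fold_r2))

    @property
    def mean_mse(self) -> float:
        return float(np.mean(self.fold_mse))


def default_grids() -> dict[str, dict[str, list[Any]]]:
    """Load the shipped default hyperparameter grids."""
    with resources.files("logbbpred.data").joinpath("default_grids.toml").open("rb") as fh:
        return tomllib.load(fh)


def load_grids(path: str | Path) -> dict[str, dict[str, list[Any]]]:
    """Load user-supplied grids from a TOML file (one table per learner)."""
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def make_estimator(name: str, params: dict[str, Any], seed: int, n_features: int):
    """Instantiate an unfitted estimator for a registered learner."""
    params = dict(params)
    if name == "lightgbm":
        from lightgbm import LGBMRegressor

        return LGBMRegressor(random_state=seed, n_jobs=1, verbose=-1, **params)
    if name == "rf":
        return RandomForestRegressor(random_state=seed, n_jobs=1, **params)
    if name == "knn":
        return KNeighborsRegressor(**params)
    if name == "mlr":
        return LinearRegression(**params)
    if name == "svm":
        return SVR(**params)
    if name == "adaboost":
        return AdaBoostRegressor(random_state=seed, **params)
    if name == "xgboost":
        from xgboost import XGBRegressor

        return XGBRegressor(random_state=seed, n_jobs=1, verbosity=0, **params)
    if name == "ann":
        params.setdefault("hidden_layer_sizes", (min(64, max(1, n_features)),))
        params.setdefault("max_iter", 2000)
        return MLPRegressor(random_state=seed, **params)
    raise UnknownLearnerError(f"unknown learner {name!r}")


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, DescriptorTable):
        return X.data
    if isinstance(X, pd.DataFrame):
        return X
    raise TypeError("X must be a DescriptorTable or pandas DataFrame with named columns")


def _validate_xy(X: pd.DataFrame, y: np.ndarray) -> None:
    if not np.isfinite(X.to_numpy(dtype=float)).all():
        raise ValueError("feature matrix contains non-finite values; prune first")
    if not np.isfinite(y).all():
        raise ValueError("target vector contains non-finite values")
    if len(y) != X.shape[0]:
        raise ValueError(f"X has {X.shape[0]} rows but y has {len(y)} values")


def train(
    spec: LearnerSpec,
    X,
    y,
    params: dict[str, Any] | None = None,
    seed: int = 0,
) -> TrainedModel:
    """Fit one learner on the full matrix; scaler statistics are stored.

    Deterministic for a fixed seed. The model remembers its feature names
    and can later be applied to any query frame containing those columns.
    """
    frame = _as_frame(X)
    y = np.asarray(y, dtype=float)
    _validate_xy(frame, y)
    merged = {**spec.fixed_params, **(params or {})}
    scaler = fit_scaler(DescriptorTable(data=frame))
    scaled = apply_scaler(DescriptorTable(data=frame), scaler)
    est = make_estimator(spec.name, merged, seed, len(scaler.names))
    est.fit(scaled.data, y)
    return TrainedModel(
        learner=spec.name,
        estimator=est,
        feature_names=list(scaler.names),
        scaler=scaler,
        metadata={"seed": seed, "params": merged, "n_train": len(y)},
    )


def predict(model: TrainedModel, X_query) -> np.ndarray:
    """Predict logBB for query rows; columns matched by name, extras ignored."""
    frame = _as_frame(X_query)
    missing = [n for n in model.feature_names if n not in frame.columns]
    if missing:
        from .errors import SchemaError

        raise SchemaError(missing)
    scaled = apply_scaler(DescriptorTable(data=frame), model.scaler)
    preds = np.asarray(model.estimator.predict(scaled.data), dtype=float)
    if not np.isfinite(preds).all():
        raise ValueError("model produced non-finite predictions")
    return preds


def kfold_indices(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Deterministic shuffled k-fold test-index partition of range(n)."""
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in kf.split(np.arange(n))]


def cross_validate(
    spec: LearnerSpec,
    X,
    y,
    k: int = 10,
    seed: int = 0,
    params: dict[str, Any] | None = None,
    prescale: bool = False,
) -> CVRecord:
    """Shuffled k-fold cross-validation reporting per-fold and mean R^2/MSE.

    Each fold fits the scaler on its training part only (unless ``prescale``
    globally standardizes first), trains the learner, and scores the held-out
    part.
    """
    frame = _as_frame(X)
    y = np.asarray(y, dtype=float)
    _validate_xy(frame, y)
    n = len(y)
    if k < 2 or k > n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    merged = {**spec.fixed_params, **(params or {})}

    if prescale:
        scaler = fit_scaler(DescriptorTable(data=frame))
        frame = apply_scaler(DescriptorTable(data=frame), scaler).data

    folds = kfold_indices(n, k, seed)
    fold_r2: list[float] = []
    fold_mse: list[float] = []
    all_idx = np.arange(n)
    for test_idx in folds:
        train_idx = np.setdiff1d(all_idx, test_idx)
        X_tr, X_te = frame.iloc[train_idx], frame.iloc[test_idx]
        y_tr, y_te = y[train_idx], y[test_idx]
        if prescale:
            est = make_estimator(spec.name, merged, seed, X_tr.shape[1])
            est.fit(X_tr, y_tr)
            preds = est.predict(X_te)
        else:
            model = train(spec, X_tr, y_tr, params=merged, seed=seed)
            preds = predict(model, X_te)
        fold_r2.append(_r2(y_te, preds))
        fold_mse.append(_mse(y_te, preds))
    return CVRecord(k=k, seed=seed, fold_r2=fold_r2, fold_mse=fold_mse, fold_test_indices=folds)


def grid_search(
    spec: LearnerSpec,
    X,
    y,
    k: int = 10,
    seed: int = 0,
    prescale: bool = False,
) -> tuple[dict[str, Any], TrainedModel, CVRecord]:
    """Exhaustive search over the grid's Cartesian product by mean CV R^2.

    Candidates are enumerated in deterministic order (sorted parameter
    names, listed value order); ties keep the first candidate. The winning
    setting is refit on the full data.
    """
    if not spec.param_grid:
        candidates: list[dict[str, Any]] = [{}]
    else:
        keys = sorted(spec.param_grid)
        candidates = [
            dict(zip(keys, combo))
            for combo in itertools.product(*(spec.param_grid[key] for key in keys))
        ]
    best: tuple[dict[str, Any], CVRecord] | None = None
    for cand in candidates:
        record = cross_validate(spec, X, y, k=k, seed=seed, params=cand, prescale=prescale)
        logger.info("grid point %s: mean CV R^2 = %.4f", cand, record.mean_r2)
        if best is None or record.mean_r2 > best[1].mean_r2:
            best = (cand, record)
    assert best is not None
    best_params, best_record = best
    model = train(spec, X, y, params=best_params, seed=seed)
    model.metadata["cv"] = {
        "k": k,
        "seed": seed,
        "mean_r2": best_record.mean_r2,
        "mean_mse": best_record.mean_mse,
    }
    model.metadata["best_params"] = best_params
    return best_params, model, best_record


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist a trained model as a single versioned archive."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "learner": model.learner,
        "estimator": model.estimator,
        "feature_names": model.feature_names,
        "scaler": model.scaler,
        "metadata": model.metadata,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> TrainedModel:
    """Load a persisted model; refuses version mismatches."""
    payload = joblib.load(path)
    version = payload.get("format_version") if isinstance(payload, dict) else None
    if version != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"model archive version {version!r} != supported {MODEL_FORMAT_VERSION}"
        )
    return TrainedModel(
        learner=payload["learner"],
        estimator=payload["estimator"],
        feature_names=payload["feature_names"],
        scaler=payload["scaler"],
        metadata=payload["metadata"],
    )
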