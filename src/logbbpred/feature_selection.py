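"""Redundancy filtering of descriptors by Pearson correlation.

Descriptor pairs whose absolute pairwise Pearson correlation exceeds a
threshold are considered redundant; of such a pair, the member with the
lower absolute correlation to the logBB target is discarded. The filter is
greedy: descriptors are visited in order of decreasing target relevance, so
a descriptor is kept iff it is not too correlated with any *more relevant*
descriptor already kept. The threshold itself is chosen by sweeping 0.1-0.9
and cross-validating a learner on each resulting feature set; the sweep
reuses one fold partition across thresholds so the comparison is paired.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DegenerateInputError
from .featurization import DescriptorTable
from .modeling import CVRecord, LearnerSpec, cross_validate

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = tuple(round(0.1 * i, 1) for i in range(1, 10))  # 0.1 .. 0.9


@dataclass
class SelectionResult:
    threshold: float
    selected_names: list[str]
    relevance: dict[str, float]  # |PCC with target| per surviving-candidate descriptor
    dropped_pairs: list[tuple[str, str, float]]  # (kept, dropped, pairwise PCC)


@dataclass
class SweepResult:
    thresholds: list[float]
    n_features: list[int]
    mean_r2: list[float]
    mean_mse: list[float]
    chosen_threshold: float
    chosen_selection: SelectionResult
    cv_records: dict[float, CVRecord] = field(default_factory=dict)


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation coefficient in [-1, 1].

    Raises
    ------
    DegenerateInputError
        If either vector is constant (zero variance).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("vectors differ in length")
    if xa.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise DegenerateInputError("constant input vector; correlation undefined")
    xc = xa - xa.mean()
    yc = ya - ya.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    return float(np.clip(r, -1.0, 1.0))


def correlation_filter(
    table: DescriptorTable, target: Sequence[float], threshold: float
) -> SelectionResult:
    """Greedy redundancy filter keeping the more target-relevant of each clash.

    Descriptors are ranked by descending ``|PCC(descriptor, target)|`` (ties
    broken lexicographically by name) and visited in that order; one is kept
    iff its absolute pairwise correlation with every already-kept descriptor
    is <= threshold. Constant columns are dropped up front with a warning.
    Every drop records the kept descriptor it conflicted with.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    y = np.asarray(target, dtype=float)
    values = table.values
    if values.shape[0] != y.size:
        raise ValueError("table rows and target length differ")
    names = table.descriptor_names

    variable = values.std(axis=0) > 0
    n_const = int((~variable).sum())
    if n_const:
        logger.warning("correlation_filter: ignoring %d constant columns", n_const)
    if not variable.any():
        raise DegenerateInputError("all descriptor columns are constant")
    if np.ptp(y) == 0:
        raise DegenerateInputError("target vector is constant")

    idx = np.flatnonzero(variable)
    sub = values[:, idx]
    sub_names = [names[j] for j in idx]

    # column-standardize once; both relevance and pairwise PCC follow by dot product
    z = (sub - sub.mean(axis=0)) / sub.std(axis=0)
    n = z.shape[0]
    yz = (y - y.mean()) / y.std()
    relevance_vec = np.abs(z.T @ yz / n)
    relevance = dict(zip(sub_names, (float(v) for v in relevance_vec)))

    order = sorted(range(len(sub_names)), key=lambda j: (-relevance_vec[j], sub_names[j]))
    kept: list[int] = []
    dropped_pairs: list[tuple[str, str, float]] = []
    for j in order:
        clash = None
        for kj in kept:
            pcc = float(z[:, kj] @ z[:, j] / n)
            if abs(pcc) > threshold:
                clash = (kj, pcc)
                break
        if clash is None:
            kept.append(j)
        else:
            kj, pcc = clash
            dropped_pairs.append((sub_names[kj], sub_names[j], pcc))
    # restore original table order among the kept descriptors
    kept_set = {sub_names[j] for j in kept}
    selected = [nm for nm in sub_names if nm in kept_set]
    return SelectionResult(
        threshold=threshold,
        selected_names=selected,
        relevance=relevance,
        dropped_pairs=dropped_pairs,
    )


def sweep_thresholds(
    table: DescriptorTable,
    target: Sequence[float],
    learner: LearnerSpec,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    k: int = 10,
    seed: int = 0,
    params: dict | None = None,
) -> SweepResult:
    """Pick the redundancy threshold by cross-validated R^2 of one learner.

    Each threshold's selected feature set is scored with the same k-fold
    partition (common seed), so per-threshold scores are paired. The chosen
    threshold maximizes mean CV R^2; ties break toward the smaller feature
    set (and then the smaller threshold). Thresholds yielding fewer than two
    features are skipped with a warning.
    """
    y = np.asarray(target, dtype=float)
    tried: list[float] = []
    n_features: list[int] = []
    mean_r2: list[float] = []
    mean_mse: list[float] = []
    selections: dict[float, SelectionResult] = {}
    records: dict[float, CVRecord] = {}
    for thr in thresholds:
        sel = correlation_filter(table, y, thr)
        if len(sel.selected_names) < 2:
            logger.warning("threshold %.2f yields <2 features; skipped", thr)
            continue
        sub = DescriptorTable(data=table.data[sel.selected_names])
        rec = cross_validate(learner, sub, y, k=k, seed=seed, params=params)
        tried.append(thr)
        n_features.append(len(sel.selected_names))
        mean_r2.append(rec.mean_r2)
        mean_mse.append(rec.mean_mse)
        selections[thr] = sel
        records[thr] = rec
        logger.info(
            "threshold %.2f: %d features, mean CV R^2 %.4f",
            thr,
            len(sel.selected_names),
            rec.mean_r2,
        )
    if not tried:
        raise DegenerateInputError("no threshold produced a usable feature set")
    best_i = min(
        range(len(tried)),
        key=lambda i: (-mean_r2[i], n_features[i], tried[i]),
    )
    chosen = tried[best_i]
    return SweepResult(
        thresholds=tried,
        n_features=n_features,
        mean_r2=mean_r2,
        mean_mse=mean_mse,
        chosen_threshold=chosen,
        chosen_selection=selections[chosen],
        cv_records=records,
    )
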