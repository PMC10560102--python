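"""Molecular descriptor computation, pruning and standardization.

Descriptors (molecular weight, logP, topological indices, ...) are computed
per compound with RDKit's descriptor set; 3D descriptors additionally need a
conformer, which is embedded deterministically from a fixed seed. Columns
with any missing or non-finite entry are pruned dataset-wide before
modeling, and retained features are standardized with training-set mean and
standard deviation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, Descriptors, Descriptors3D

from .chem_io import MoleculeRecord
from .errors import EmptyDatasetError

logger = logging.getLogger(__name__)


@dataclass
class DescriptorTable:
    """Compounds x named numeric descriptors, NaN marking failed computations."""

    data: pd.DataFrame  # index: compound ids; columns: descriptor names; float64

    @property
    def compound_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def missing_mask(self) -> np.ndarray:
        """True where an entry is missing or non-finite."""
        return ~np.isfinite(self.values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class ScalerParams:
    """Per-descriptor training-set mean and sample (ddof=1) standard deviation."""

    names: list[str]
    mean: np.ndarray
    sd: np.ndarray  # strictly positive; zero-variance columns dropped at fit


def compute_descriptors(
    records: Sequence[MoleculeRecord],
    include_3d: bool = False,
    conformer_seed: int = 42,
) -> DescriptorTable:
    """Compute the RDKit 2D descriptor set (and optionally 3D) per compound.

    Descriptors that fail to compute yield NaN entries, never silent zeros.
    A compound whose every descriptor fails is excluded with a warning. 3D
    descriptors use an ETKDG-embedded conformer seeded by ``conformer_seed``
    so repeat runs are identical; a molecule that fails to embed gets NaN in
    every 3D column.
    """
    rows: list[dict[str, float]] = []
    ids: list[str] = []
    for rec in records:
        mol = Chem.MolFromSmiles(rec.smiles_canonical)
        if mol is None:
            logger.warning("compound %s: SMILES no longer parseable, excluded", rec.id)
            continue
        vals = Descriptors.CalcMolDescriptors(mol, missingVal=np.nan)
        if include_3d:
            vals.update(_descriptors_3d(mol, conformer_seed))
        row = {k: _as_float(v) for k, v in vals.items()}
        if all(not np.isfinite(v) for v in row.values()):
            logger.warning("compound %s: every descriptor failed, excluded", rec.id)
            continue
        rows.append(row)
        ids.append(rec.id)
    if not rows:
        raise EmptyDatasetError("no compound yielded any descriptor")
    frame = pd.DataFrame(rows, index=ids, dtype=float)
    return DescriptorTable(data=frame)


def _as_float(v) -> float:
    try:
        out = float(v)
    except (TypeError, ValueError):
        return float("nan")
    return out


def _descriptors_3d(mol: Chem.Mol, seed: int) -> dict[str, float]:
    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    nan3d = {name: float("nan") for name, _ in Descriptors3D.descList}
    if AllChem.EmbedMolecule(molh, params) != 0:
        logger.warning("conformer embedding failed; 3D descriptors set to NaN")
        return nan3d
    try:
        return Descriptors3D.CalcMolDescriptors3D(molh)
    except Exception:  # degenerate geometries raise from several backends
        return nan3d


def prune_missing(table: DescriptorTable) -> DescriptorTable:
    """Drop every descriptor column containing >= 1 missing/non-finite entry.

    NaN and +/-inf are treated alike: both are unusable for model fitting.
    Compound rows are unchanged. Idempotent.
    """
    finite = np.isfinite(table.values).all(axis=0)
    kept = [n for n, ok in zip(table.descriptor_names, finite) if ok]
    dropped = table.shape[1] - len(kept)
    if dropped:
        logger.info("prune_missing: dropped %d/%d descriptors", dropped, table.shape[1])
    if not kept:
        raise EmptyDatasetError("all descriptor columns contain missing values")
    return DescriptorTable(data=table.data[kept].copy())


def fit_scaler(table: DescriptorTable) -> ScalerParams:
    """Fit standard-scaling statistics on training rows.

    Zero-variance columns are dropped with a warning before scaling (their
    sd is 0, so they carry no information and cannot be standardized).
    """
    values = table.values
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1) if values.shape[0] > 1 else np.zeros(values.shape[1])
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("fit_scaler: dropping %d zero-variance columns", n_dropped)
    names = [n for n, k in zip(table.descriptor_names, keep) if k]
    if not names:
        raise EmptyDatasetError("no non-constant descriptor columns to scale")
    return ScalerParams(names=names, mean=mean[keep], sd=sd[keep])


def apply_scaler(table: DescriptorTable, params: ScalerParams) -> DescriptorTable:
    """Standardize with *training* statistics: (x - mean) / sd per column.

    Held-out rows are transformed with the statistics stored in ``params``,
    never their own. Columns are subset to the scaler's retained names.
    """
    sub = table.data[params.names]
    scaled = (sub.to_numpy(dtype=float) - params.mean) / params.sd
    return DescriptorTable(data=pd.DataFrame(scaled, index=sub.index, columns=params.names))


def inverse_scaler(table: DescriptorTable, params: ScalerParams) -> DescriptorTable:
    """Undo :func:`apply_scaler`; apply-then-inverse is identity within 1e-9."""
    sub = table.data[params.names]
    raw = sub.to_numpy(dtype=float) * params.sd + params.mean
    return DescriptorTable(data=pd.DataFrame(raw, index=sub.index, columns=params.names))
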