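"""Reading, validating and writing compound datasets.

Compounds are exchanged as SMILES strings; every record is canonicalized on
ingestion so that downstream fingerprinting and deduplication see one string
per molecule. Unparseable rows are skipped (with a logged warning and a row
report), not fatal, so large screening files proceed.
"""
from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit import RDLogger

from .errors import EmptyDatasetError, MissingColumnError, SmilesParseError

logger = logging.getLogger(__name__)

# RDKit writes its own parse complaints to stderr; we report rejections
# ourselves with row numbers, so silence the duplicate channel.
RDLogger.DisableLog("rdApp.error")

PREDICTION_FLOAT_FMT = "%.6f"


@dataclass
class MoleculeRecord:
    """One compound: identifier, raw and canonical SMILES, optional logBB.

    logBB is log10(brain concentration / blood concentration), dimensionless.
    """

    id: str
    smiles_raw: str
    smiles_canonical: str
    logbb: float | None = None

    def __post_init__(self) -> None:
        if self.logbb is not None and not math.isfinite(self.logbb):
            raise ValueError(f"logBB for {self.id!r} is not finite: {self.logbb}")


@dataclass
class RejectedRow:
    """A row excluded during ingestion, with its 1-based data row number."""

    row_number: int
    smiles: str
    reason: str


@dataclass
class ReadReport:
    """Bookkeeping from :func:`read_dataset`: accepted + rejected = input rows."""

    n_rows: int = 0
    rejected: list[RejectedRow] = field(default_factory=list)
    duplicates: list[str] = field(default_factory=list)


def canonicalize(smiles: str) -> str:
    """Return RDKit's canonical SMILES; idempotent, same molecule -> same string.

    Raises
    ------
    SmilesParseError
        If the string is empty or does not parse.
    """
    if not smiles or not smiles.strip():
        raise SmilesParseError(smiles, "empty string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    return Chem.MolToSmiles(mol)


def read_dataset(
    path: str | Path,
    format: str = "csv",
    smiles_column: str = "smiles",
    logbb_column: str = "logbb",
    drop_duplicates: bool = True,
    report: ReadReport | None = None,
) -> list[MoleculeRecord]:
    """Read a compound dataset from a CSV or SMI file.

    CSV requires a header with a SMILES column (name configurable) and an
    optional logBB column. SMI is one SMILES per line with an optional
    whitespace-separated id. Rows whose SMILES fail to parse are excluded and
    reported; duplicate canonical SMILES keep the first occurrence.

    Parameters
    ----------
    report
        Optional mutable report; filled with row counts, rejections and
        duplicate warnings.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"dataset file not found: {path}")
    if format not in ("csv", "smi"):
        raise ValueError(f"unknown format {format!r}; expected 'csv' or 'smi'")
    if report is None:
        report = ReadReport()

    rows: list[tuple[str, str | None, float | None]] = []  # (id, smiles, logbb)
    if format == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or smiles_column not in reader.fieldnames:
                raise MissingColumnError(
                    f"column {smiles_column!r} not found in {path} "
                    f"(columns: {reader.fieldnames})"
                )
            has_logbb = logbb_column in (reader.fieldnames or [])
            id_col = "id" if "id" in (reader.fieldnames or []) else None
            for i, row in enumerate(reader, start=1):
                smi = (row.get(smiles_column) or "").strip()
                if not smi:
                    continue
                logbb: float | None = None
                if has_logbb:
                    raw = (row.get(logbb_column) or "").strip()
                    if raw:
                        logbb = float(raw)
                rid = row[id_col].strip() if id_col and row.get(id_col) else f"cmpd_{i}"
                rows.append((rid, smi, logbb))
    else:  # smi
        with open(path, encoding="utf-8") as fh:
            for i, line in enumerate(fh, start=1):
                parts = line.split()
                if not parts:
                    continue
                smi = parts[0]
                rid = parts[1] if len(parts) > 1 else f"cmpd_{i}"
                rows.append((rid, smi, None))

    report.n_rows = len(rows)
    records: list[MoleculeRecord] = []
    seen: set[str] = set()
    for row_no, (rid, smi, logbb) in enumerate(rows, start=1):
        try:
            canon = canonicalize(smi)
        except SmilesParseError as exc:
            logger.warning("row %d: skipping unparseable SMILES %r", row_no, smi)
            report.rejected.append(RejectedRow(row_no, smi, str(exc)))
            continue
        if drop_duplicates and canon in seen:
            logger.warning("row %d: duplicate canonical SMILES %r, keeping first", row_no, canon)
            report.duplicates.append(canon)
            continue
        seen.add(canon)
        records.append(MoleculeRecord(id=rid, smiles_raw=smi, smiles_canonical=canon, logbb=logbb))

    if not records:
        raise EmptyDatasetError(f"no parseable compounds in {path}")
    return records


def write_dataset(records: Sequence[MoleculeRecord], path: str | Path) -> None:
    """Write records back to CSV (id, smiles, logbb); round-trips with read_dataset."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "smiles", "logbb"])
        for rec in records:
            logbb = "" if rec.logbb is None else PREDICTION_FLOAT_FMT % rec.logbb
            writer.writerow([rec.id, rec.smiles_canonical, logbb])


def write_predictions(
    records: Sequence[MoleculeRecord],
    predictions: Iterable[float],
    labels: Iterable[str],
    path: str | Path,
) -> None:
    """Write a prediction table: id, smiles, predicted_logbb, bbb_class.

    Fixed float formatting makes repeat runs byte-identical.
    """
    predictions = list(predictions)
    labels = list(labels)
    if not (len(records) == len(predictions) == len(labels)):
        raise ValueError(
            f"length mismatch: {len(records)} records, "
            f"{len(predictions)} predictions, {len(labels)} labels"
        )
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "smiles", "predicted_logbb", "bbb_class"])
        for rec, pred, lab in zip(records, predictions, labels):
            writer.writerow([rec.id, rec.smiles_canonical, PREDICTION_FLOAT_FMT % pred, lab])


def read_predictions(path: str | Path) -> list[dict]:
    """Read back a prediction table written by :func:`write_predictions`."""
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(
                {
                    "id": row["id"],
                    "smiles": row["smiles"],
                    "predicted_logbb": float(row["predicted_logbb"]),
                    "bbb_class": row["bbb_class"],
                }
            )
    return out
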