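"""Circular fingerprints and Tanimoto-similarity curation.

Compounds are encoded as 1024-bit Morgan fingerprints of radius 2 (the open
ECFP4 equivalent) and compared by Tanimoto similarity

    T(a, b) = N_c / (N_a + N_b - N_c)

where N_a and N_b are the on-bit counts of the two molecules and N_c the
count of bits on in both. Datasets are curated by a greedy leader pass: a
compound is discarded when its similarity to an already-kept compound
exceeds the cutoff (default 0.85, the conventional "similar" threshold).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .chem_io import MoleculeRecord
from .errors import SmilesParseError

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 0.85
N_BITS = 1024


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length binary substructure fingerprint."""

    bits: np.ndarray  # uint8 0/1 vector, length n_bits

    @property
    def n_bits(self) -> int:
        return self.bits.shape[0]

    @property
    def n_on(self) -> int:
        return int(self.bits.sum())

    def __eq__(self, other: object) -> bool:  # frozen dataclass + ndarray
        return isinstance(other, Fingerprint) and np.array_equal(self.bits, other.bits)

    def __hash__(self) -> int:
        return hash(self.bits.tobytes())


@dataclass(frozen=True)
class SimilarityDecision:
    """Outcome of comparing one compound against a kept compound."""

    pair: tuple[str, str]  # (kept id, candidate id)
    t: float
    discarded_id: str | None  # set iff t > cutoff


def fingerprint(
    record: MoleculeRecord | str, radius: int = 2, n_bits: int = N_BITS
) -> Fingerprint:
    """Morgan/circular fingerprint of a record (or SMILES string).

    Deterministic: identical canonical SMILES give bitwise-identical vectors.
    """
    smiles = record if isinstance(record, str) else record.smiles_canonical
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles, "fingerprinting a record that should be pre-validated")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    bv = gen.GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=np.uint8)
    for bit in bv.GetOnBits():
        arr[bit] = 1
    return Fingerprint(bits=arr)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto similarity N_c / (N_a + N_b - N_c); 0 for two empty fingerprints."""
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint length mismatch: {a.n_bits} vs {b.n_bits}")
    n_c = int(np.sum(a.bits & b.bits))
    denom = a.n_on + b.n_on - n_c
    if denom == 0:
        return 0.0
    return n_c / denom


def deduplicate(
    records: Sequence[MoleculeRecord],
    cutoff: float = DEFAULT_CUTOFF,
    radius: int = 2,
    n_bits: int = N_BITS,
) -> tuple[list[MoleculeRecord], list[SimilarityDecision]]:
    """Greedy leader-pass deduplication in input order.

    A record is kept iff its Tanimoto similarity to every previously kept
    record is <= cutoff (strictly greater discards). Every discard is
    recorded with the offending kept record and the similarity. The kept set
    therefore has all pairwise similarities <= cutoff, and the pass is
    idempotent.
    """
    kept: list[MoleculeRecord] = []
    kept_fps: list[Fingerprint] = []
    decisions: list[SimilarityDecision] = []
    for rec in records:
        fp = fingerprint(rec, radius=radius, n_bits=n_bits)
        if fp.n_on == 0:
            logger.warning("compound %s has an all-zero fingerprint", rec.id)
        discard_against: tuple[str, float] | None = None
        for krec, kfp in zip(kept, kept_fps):
            t = tanimoto(kfp, fp)
            if t > cutoff:
                discard_against = (krec.id, t)
                break
        if discard_against is None:
            kept.append(rec)
            kept_fps.append(fp)
        else:
            kid, t = discard_against
            decisions.append(SimilarityDecision(pair=(kid, rec.id), t=t, discarded_id=rec.id))
    return kept, decisions


def screen_against_reference(
    query: Sequence[MoleculeRecord],
    reference: Sequence[MoleculeRecord],
    cutoff: float = DEFAULT_CUTOFF,
    radius: int = 2,
    n_bits: int = N_BITS,
) -> list[MoleculeRecord]:
    """Keep query compounds whose max similarity to the reference set is <= cutoff.

    Used to build a leakage-free external test set: anything too similar to a
    training compound is removed. The reference set is never modified.
    """
    if not reference:
        logger.warning("empty reference set: all %d query compounds kept", len(query))
        return list(query)
    ref_fps = [fingerprint(r, radius=radius, n_bits=n_bits) for r in reference]
    kept = []
    for rec in query:
        fp = fingerprint(rec, radius=radius, n_bits=n_bits)
        if all(tanimoto(rfp, fp) <= cutoff for rfp in ref_fps):
            kept.append(rec)
    return kept
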