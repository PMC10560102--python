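"""Self-contained synthetic fixtures for every pipeline stage.

Two generators cover the two kinds of structure the pipeline exploits:

* homologous SMILES series (alkanes/alcohols) whose adjacent members are
  highly fingerprint-similar while cross-series pairs are not, exercising
  both the discard and keep branches of Tanimoto deduplication;
* descriptor tables with block-redundant features and a known
  linear-plus-noise logBB signal, giving the correlation filter and the
  cross-validation harness analytic expectations (block recovery, an R^2
  ceiling of 1 - noise_sd^2 / var(y)).

Everything is reproducible from a single integer seed. The SMILES are
chemically trivial on purpose: descriptor validity, not pharmacology, is
under test.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem_io import MoleculeRecord, canonicalize
from .featurization import DescriptorTable

# observed logBB envelope of curated experimental datasets, log10 units
LOGBB_RANGE = (-2.69, 1.7)

# small, structurally diverse molecules: cross-pairs sit well below the 0.85
# similarity cutoff, so they survive deduplication alongside one homolog each
_AROMATICS = [
    "c1ccccc1",  # benzene
    "c1ccncc1",  # pyridine
    "c1ccc2ccccc2c1",  # naphthalene
    "c1ccsc1",  # thiophene
    "C1CCNCC1",  # piperidine
    "c1ccc(Cl)cc1",  # chlorobenzene
    "Cc1ccccc1",  # toluene
    "Oc1ccccc1",  # phenol
    "Nc1ccccc1",  # aniline
    "OC(=O)c1ccccc1",  # benzoic acid
    "CC(=O)Nc1ccccc1",  # acetanilide
    "c1ccoc1",  # furan
    "C1CCOC1",  # tetrahydrofuran
    "C1CCCCC1",  # cyclohexane
    "CC(C)=O",  # acetone
    "CC#N",  # acetonitrile
    "CS(C)=O",  # DMSO
    "O=C1CCCCC1",  # cyclohexanone
    "OCC(O)CO",  # glycerol
    "CC(=O)OCC",  # ethyl acetate
    "FC(F)(F)c1ccccc1",  # benzotrifluoride
    "O=[N+]([O-])c1ccccc1",  # nitrobenzene
    "COc1ccccc1",  # anisole
    "c1cnc2[nH]ccc2c1",  # azaindole
]


@dataclass
class SyntheticSpec:
    """Parameters of the block-redundant regression generator."""

    n_compounds: int = 200
    n_signal_features: int = 3
    clones_per_block: int = 10
    intra_block_corr: float = 0.95
    noise_sd: float = 1.0  # logBB units
    coefficients: tuple[float, ...] = (1.0, -0.7, 0.5)
    n_noise_features: int = 5
    seed: int = 0
    target_range: tuple[float, float] | None = None  # affine-rescale y into this span

    def __post_init__(self) -> None:
        if not 0.0 <= self.intra_block_corr <= 1.0:
            raise ValueError("intra_block_corr must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.coefficients) != self.n_signal_features:
            raise ValueError("coefficients length must equal n_signal_features")
        if self.n_compounds < 3:
            raise ValueError("need at least 3 compounds")


@dataclass
class TruthRecord:
    """Ground truth of a generated dataset, for oracle-style assertions."""

    blocks: dict[str, list[str]]  # generator feature -> [generator, clones...]
    coefficients: dict[str, float]
    noise_sd: float
    r2_ceiling: float  # 1 - noise_sd^2 / var(y), with analytic var(y)
    noise_features: list[str] = field(default_factory=list)


def noise_sd_for_ceiling(coefficients, ceiling: float) -> float:
    """Noise sd giving an analytic out-of-sample R^2 ceiling for unit-normal signals.

    With y = sum(beta_i z_i) + eps and independent standard-normal z,
    var(y) = |beta|^2 + sd^2, so ceiling = |beta|^2 / (|beta|^2 + sd^2).
    """
    if not 0.0 < ceiling <= 1.0:
        raise ValueError("ceiling must be in (0, 1]")
    b2 = float(np.sum(np.square(coefficients)))
    if ceiling == 1.0:
        return 0.0
    return float(np.sqrt(b2 * (1.0 - ceiling) / ceiling))


def make_regression_dataset(
    spec: SyntheticSpec,
) -> tuple[DescriptorTable, np.ndarray, TruthRecord]:
    """Generate a descriptor table with block-correlated features and a linear target.

    Each signal feature ``sig_i`` is standard normal; its clones are
    ``rho * sig_i + sqrt(1 - rho^2) * eps`` so each clone correlates with its
    generator at exactly ``rho = intra_block_corr`` (clone-clone correlation
    is rho^2). Unrelated noise features are standard normal. The target is
    ``y = sum(coeff_i * sig_i) + N(0, noise_sd)``, optionally rescaled into
    ``target_range`` (affine maps leave R^2 unchanged).
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_compounds, spec.n_signal_features
    rho = spec.intra_block_corr
    z = rng.standard_normal((n, p))

    columns: dict[str, np.ndarray] = {}
    blocks: dict[str, list[str]] = {}
    for i in range(p):
        gen_name = f"sig_{i}"
        columns[gen_name] = z[:, i]
        members = [gen_name]
        for c in range(spec.clones_per_block):
            eps = rng.standard_normal(n)
            name = f"sig_{i}_clone_{c}"
            columns[name] = rho * z[:, i] + np.sqrt(1.0 - rho**2) * eps
            members.append(name)
        blocks[gen_name] = members
    noise_names = []
    for j in range(spec.n_noise_features):
        name = f"noise_{j}"
        columns[name] = rng.standard_normal(n)
        noise_names.append(name)

    beta = np.asarray(spec.coefficients, dtype=float)
    y = z @ beta + rng.normal(0.0, spec.noise_sd, size=n)
    if spec.target_range is not None:
        lo, hi = spec.target_range
        y = lo + (y - y.min()) * (hi - lo) / (y.max() - y.min())

    var_y = float(np.sum(beta**2) + spec.noise_sd**2)
    ceiling = 1.0 - spec.noise_sd**2 / var_y if var_y > 0 else 0.0
    truth = TruthRecord(
        blocks=blocks,
        coefficients={f"sig_{i}": float(beta[i]) for i in range(p)},
        noise_sd=spec.noise_sd,
        r2_ceiling=ceiling,
        noise_features=noise_names,
    )
    ids = [f"cmpd_{i}" for i in range(n)]
    frame = pd.DataFrame(columns, index=ids, dtype=float)
    return DescriptorTable(data=frame), y, truth


def make_smiles_series(kind: str = "alkanes", n: int = 10) -> list[str]:
    """Homologous SMILES series with controlled fingerprint similarity.

    ``alkanes`` and ``alcohols`` are chain homologs (adjacent members highly
    similar); ``mixed`` interleaves both series with small aromatics so that
    cross-pairs fall below the 0.85 similarity cutoff.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if kind == "alkanes":
        return ["C" * (k + 6) for k in range(n)]
    if kind == "alcohols":
        return ["O" + "C" * (k + 6) for k in range(n)]
    if kind == "mixed":
        pool: list[str] = []
        n_each = max(1, n // 6)
        pool.extend(make_smiles_series("alkanes", n_each))
        pool.extend(make_smiles_series("alcohols", n_each))
        pool.extend(_AROMATICS[: max(1, n - 2 * n_each)])
        while len(pool) < n:  # top up with longer homologs
            pool.append("C" * (len(pool) + 6))
        return pool[:n]
    raise ValueError(f"unknown series kind {kind!r}")


def make_smiles_dataset(
    kind: str = "mixed", n: int = 30, seed: int = 0, noise_sd: float = 0.3
) -> list[MoleculeRecord]:
    """SMILES series with an attached synthetic logBB signal.

    logBB decreases linearly with heavy-atom count (larger molecules cross
    membranes less readily in this toy model) plus Gaussian noise, affinely
    mapped into the experimental envelope [-2.69, 1.7] so that binarization
    at -1 populates both permeability classes.
    """
    from rdkit import Chem

    rng = np.random.default_rng(seed)
    smiles = make_smiles_series(kind, n)
    sizes = np.array(
        [Chem.MolFromSmiles(s).GetNumHeavyAtoms() for s in smiles], dtype=float
    )
    y = -sizes + rng.normal(0.0, noise_sd, size=len(smiles))
    lo, hi = LOGBB_RANGE
    y = lo + (y - y.min()) * (hi - lo) / (y.max() - y.min())
    records = []
    for i, (smi, val) in enumerate(zip(smiles, y)):
        records.append(
            MoleculeRecord(
                id=f"syn_{i}",
                smiles_raw=smi,
                smiles_canonical=canonicalize(smi),
                logbb=float(round(val, 6)),
            )
        )
    return records
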