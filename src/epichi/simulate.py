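"""Two-locus penetrance-model simulator for case/control GWAS benchmarks.

Each simulated dataset mimics the structure of the standard epistasis
benchmark: m SNPs (1000 by default) over a balanced set of cases and
controls, where exactly one pair of SNPs — the first and the last column
by default — jointly influences disease through a 3 x 3 penetrance table
indexed by the two genotypes.  All other SNPs are drawn independently
under Hardy-Weinberg equilibrium at the setting's allele frequency and
carry no association.

Case/control ascertainment is by rejection sampling: genotype pairs for
the interacting loci are drawn from the HWE product distribution, disease
status is assigned with probability penetrance[a][b], and draws are
accepted into the case or control stratum until both reach their target
size.  This fixes the class totals exactly, as a retrospective
case/control design does.

Four named model families are provided (multiplicative, two
threshold-epistasis patterns, and exclusive-OR).  The benchmark that this
generator emulates defines its models through externally published
penetrance tables that are not restated here; the built-in defaults
reproduce the qualitative patterns (see :func:`default_penetrance`) and
any exact 3 x 3 table can be supplied through :class:`DiseaseModel`.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterator

import numpy as np

from .gwas_io import GwasMatrix, write_numeric_gwas

__all__ = [
    "MODEL_NAMES",
    "DiseaseModel",
    "SimulationConfig",
    "genotype_freqs_hwe",
    "default_penetrance",
    "simulate_dataset",
    "simulate_suite",
    "write_suite",
]

MODEL_NAMES = ("multiplicative", "epistasis_m2", "classical_epistasis", "xor")


def genotype_freqs_hwe(maf: float) -> tuple[float, float, float]:
    """Hardy-Weinberg genotype frequencies ((1-p)^2, 2p(1-p), p^2) at allele frequency p."""
    if not 0 < maf <= 0.5:
        raise ValueError(f"minor allele frequency must lie in (0, 0.5], got {maf!r}")
    q = 1.0 - maf
    return (q * q, 2.0 * maf * q, maf * maf)


def default_penetrance(
    model_name: str,
    maf: float,
    effect_size: float = 0.4,
    base_risk: float = 0.05,
) -> np.ndarray:
    """Built-in 3 x 3 penetrance table for a named two-locus model.

    ``multiplicative``
        pen[a][b] = base_risk * (1 + effect_size)^(a+b), capped at 1:
        risk multiplies per allele copy at either locus (effect_size = 0
        gives a constant-null table).
    ``epistasis_m2`` and ``classical_epistasis``
        dominant-threshold epistasis: risk is base_risk + effect_size when
        both loci carry at least one risk allele (a >= 1 and b >= 1) and
        base_risk otherwise.  The two names share this default pattern;
        they differ in the exact published tables of the originating
        benchmark, which can be passed explicitly via
        :class:`DiseaseModel`.
    ``xor``
        risk is base_risk + effect_size when exactly one locus carries a
        risk allele (a >= 1 xor b >= 1) — joint effect with weak marginals.

    effect_size is the penetrance gap between the elevated and baseline
    cells (the multiplicative per-allele factor minus one for the
    multiplicative model).
    """
    if effect_size < 0:
        raise ValueError(f"effect_size must be non-negative, got {effect_size!r}")
    if not 0 < base_risk < 1:
        raise ValueError(f"base_risk must lie in (0, 1), got {base_risk!r}")
    a = np.arange(3)[:, None]
    b = np.arange(3)[None, :]
    if model_name == "multiplicative":
        pen = np.minimum(base_risk * (1.0 + effect_size) ** (a + b), 1.0)
    elif model_name in ("epistasis_m2", "classical_epistasis"):
        pen = np.where((a >= 1) & (b >= 1), base_risk + effect_size, base_risk)
    elif model_name == "xor":
        pen = np.where((a >= 1) ^ (b >= 1), base_risk + effect_size, base_risk)
    else:
        raise ValueError(f"unknown model {model_name!r}; expected one of {MODEL_NAMES}")
    pen = pen.astype(float)
    if pen.max() > 1:
        raise ValueError("penetrance exceeds 1; lower base_risk or effect_size")
    return pen


@dataclasses.dataclass
class DiseaseModel:
    """Two-locus disease model: a 3 x 3 penetrance table at a given allele frequency."""

    name: str
    penetrance: np.ndarray
    maf: float

    def __post_init__(self) -> None:
        pen = np.asarray(self.penetrance, dtype=float)
        if pen.shape != (3, 3):
            raise ValueError(f"penetrance table must be 3x3, got {pen.shape}")
        if pen.min() < 0 or pen.max() > 1:
            raise ValueError("penetrance entries must lie in [0, 1]")
        if not 0 < self.maf <= 0.5:
            raise ValueError(f"maf must lie in (0, 0.5], got {self.maf!r}")
        self.penetrance = pen

    @classmethod
    def from_name(
        cls, name: str, maf: float, effect_size: float = 0.4, base_risk: float = 0.05
    ) -> "DiseaseModel":
        return cls(name=name, penetrance=default_penetrance(name, maf, effect_size, base_risk), maf=maf)


@dataclasses.dataclass
class SimulationConfig:
    """One benchmark setting: a model plus dataset dimensions and replication."""

    model: DiseaseModel
    n_cases: int = 400
    n_controls: int = 400
    m_snps: int = 1000
    n_datasets: int = 100
    interacting_indices: tuple[int, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("both classes must be non-empty")
        if self.m_snps < 2:
            raise ValueError("need at least two SNPs")
        if self.n_datasets < 1:
            raise ValueError("n_datasets must be positive")
        if self.interacting_indices is None:
            self.interacting_indices = (0, self.m_snps - 1)
        i, j = self.interacting_indices
        if not (0 <= i < j < self.m_snps):
            raise ValueError(f"invalid interacting pair {self.interacting_indices!r}")


def _sample_interacting(
    rng: np.random.Generator,
    model: DiseaseModel,
    n_cases: int,
    n_controls: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample (a, b) genotype pairs stratified by disease status.

    Returns (n, 2) arrays for the case and control strata.
    """
    freqs = np.array(genotype_freqs_hwe(model.maf))
    pen = model.penetrance
    # mean disease probability under the genotype-pair distribution
    joint = np.outer(freqs, freqs)
    mean_pen = float((joint * pen).sum())
    if mean_pen == 0.0 and n_cases > 0:
        raise ValueError("penetrance is identically 0: cannot fill the case stratum")
    if mean_pen == 1.0 and n_controls > 0:
        raise ValueError("penetrance is identically 1: cannot fill the control stratum")
    cases = np.empty((0, 2), dtype=np.int8)
    controls = np.empty((0, 2), dtype=np.int8)
    need_rate = max(min(mean_pen, 1 - mean_pen), 1e-3)
    while cases.shape[0] < n_cases or controls.shape[0] < n_controls:
        batch = int(max(n_cases + n_controls, 1000) / need_rate) + 1
        batch = min(batch, 4_000_000)
        a = rng.choice(3, size=batch, p=freqs).astype(np.int8)
        b = rng.choice(3, size=batch, p=freqs).astype(np.int8)
        diseased = rng.random(batch) < pen[a, b]
        pairs = np.column_stack([a, b])
        if cases.shape[0] < n_cases:
            cases = np.concatenate([cases, pairs[diseased]])
        if controls.shape[0] < n_controls:
            controls = np.concatenate([controls, pairs[~diseased]])
    return cases[:n_cases], controls[:n_controls]


def simulate_dataset(config: SimulationConfig, dataset_index: int) -> GwasMatrix:
    """Draw one replicate dataset, reproducible from (config.seed, dataset_index).

    Cases occupy rows 0..n_cases-1.  The interacting columns are sampled
    jointly with disease status; all other columns are independent HWE
    draws shared by both strata (no association).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), int(dataset_index)]))
    n = config.n_cases + config.n_controls
    freqs = np.array(genotype_freqs_hwe(config.model.maf))
    G = rng.choice(3, size=(n, config.m_snps), p=freqs).astype(np.int8)
    case_pairs, control_pairs = _sample_interacting(
        rng, config.model, config.n_cases, config.n_controls
    )
    i, j = config.interacting_indices
    G[: config.n_cases, i] = case_pairs[:, 0]
    G[: config.n_cases, j] = case_pairs[:, 1]
    G[config.n_cases :, i] = control_pairs[:, 0]
    G[config.n_cases :, j] = control_pairs[:, 1]
    return GwasMatrix(genotypes=G, n_cases=config.n_cases)


def simulate_suite(config: SimulationConfig) -> Iterator[tuple[int, GwasMatrix]]:
    """Yield (dataset_index, GwasMatrix) for every replicate of the setting."""
    for d in range(config.n_datasets):
        yield d, simulate_dataset(config, d)


def write_suite(config: SimulationConfig, out_dir: str | Path, dialect: str = "compact") -> Path:
    """Write all replicate datasets as numeric text plus a JSON truth sidecar.

    Returns the path of the truth file.  Dataset d goes to
    ``dataset_<d>.txt``; the sidecar records the interacting pair, model
    name, allele frequency, class sizes and master seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for d, gwas in simulate_suite(config):
        write_numeric_gwas(gwas, out / f"dataset_{d}.txt", dialect=dialect)
    truth = {
        "model": config.model.name,
        "maf": config.model.maf,
        "n_cases": config.n_cases,
        "n_controls": config.n_controls,
        "m_snps": config.m_snps,
        "n_datasets": config.n_datasets,
        "interacting_pair": list(config.interacting_indices),
        "seed": config.seed,
        "dialect": dialect,
    }
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=2) + "\n")
    return truth_path
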