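"""Case/control labeling and dataset assembly.

The epistasis signal enters the simulated data only through labeling: a
sample's probability of being a case is the penetrance-table cell of its
combination genotype at the K model loci.  Genotypes themselves are never
rewritten.  Balanced datasets are filled by rejection sampling against the
case and control quotas; unbalanced datasets label a fixed number of samples
once and keep the natural proportions.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import models
from .exceptions import ModelError, QuotaError
from .io import load_sampling_dataset, write_genotype_matrix, write_json_metadata
from .models import PenetranceTable
from .resampling import (
    GenotypeMatrix,
    SamplingPool,
    build_pool,
    generate_rows,
    match_loci_by_maf,
)

__all__ = [
    "SimulationConfig",
    "LabeledDataset",
    "SimulationResult",
    "label_row",
    "label_rows",
    "assemble_balanced",
    "assemble_unbalanced",
    "run_simulation",
    "write_dataset",
]

logger = logging.getLogger(__name__)

#: Rejection-sampling attempt cap, as a multiple of the total quota.
QUOTA_ATTEMPT_FACTOR = 1000

# SeedSequence spawn keys for the independent random streams of one run.
_POOL_KEY, _MATCH_KEY, _REPLICATE_KEY = 0, 1, 2


@dataclass
class SimulationConfig:
    """Every user-facing parameter of one simulation run."""

    alpha: float
    target_mode: str  # "prevalence" | "heritability"
    target_value: float
    mafs: tuple[float, ...]
    n_snps: int
    n_cases: int = 0
    n_controls: int = 0
    n_total: int = 0
    balanced: bool = True
    n_datasets: int = 1
    seed: int = 0
    len_min: int = 10
    len_max: int = 30
    shared_breakpoints: bool = False
    normalize_mode: str = "one_plus_max"
    model_path: str | None = None
    model_type: str | None = None
    order: int | None = None
    sampling_path: str | None = None
    labels_path: str | None = None
    output_dir: str | None = None

    def __post_init__(self):
        if self.target_mode not in ("prevalence", "heritability"):
            raise ModelError(
                "target_mode must be 'prevalence' or 'heritability', got "
                f"{self.target_mode!r}"
            )
        if not 0.0 < self.alpha < 1.0:
            raise ModelError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not 0.0 < self.target_value < 1.0:
            raise ModelError(
                f"target {self.target_mode} must lie in (0, 1), got {self.target_value}"
            )
        self.mafs = tuple(float(m) for m in self.mafs)
        if not self.mafs or any(not 0.0 < m <= 0.5 for m in self.mafs):
            raise ModelError("model MAFs must lie in (0, 0.5]")
        if (self.model_path is None) == (self.model_type is None):
            raise ModelError(
                "specify exactly one of model_path or model_type (+ order)"
            )
        if self.model_type is not None:
            if self.order is None:
                raise ModelError("order is required with a canonical model_type")
            if self.order != len(self.mafs):
                raise ModelError(
                    f"order {self.order} does not match {len(self.mafs)} MAFs"
                )
        if self.balanced:
            if self.n_cases < 1 or self.n_controls < 1:
                raise ModelError("balanced mode needs n_cases >= 1 and n_controls >= 1")
        elif self.n_total < 1:
            raise ModelError("unbalanced mode needs n_total >= 1")
        if self.n_snps < len(self.mafs):
            raise ModelError("n_snps must be at least the model order")
        if self.n_datasets < 1:
            raise ModelError("n_datasets must be >= 1")
        if not 1 <= self.len_min <= self.len_max:
            raise ModelError("need 1 <= len_min <= len_max")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "SimulationConfig":
        """Build a config from a YAML key-value file; keyword overrides win."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ModelError(f"config file {path} must be a key-value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ModelError(f"unknown config keys in {path}: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


@dataclass
class LabeledDataset:
    """Simulated genotypes plus labels, model loci and the table that labeled them."""

    genotypes: GenotypeMatrix
    model_loci: np.ndarray
    table: PenetranceTable

    @property
    def labels(self) -> np.ndarray:
        return self.genotypes.labels


@dataclass
class SimulationResult:
    """Everything one :func:`run_simulation` call produced."""

    datasets: list[LabeledDataset]
    table: PenetranceTable
    model_loci: np.ndarray
    achieved_prevalence: float
    achieved_heritability: float
    config: SimulationConfig
    output_paths: list[Path] = field(default_factory=list)


def _combo_indices(rows: np.ndarray, loci: Sequence[int], order: int) -> np.ndarray:
    codes = rows[:, np.asarray(loci, dtype=np.int64)].astype(np.int64) - 1
    powers = 3 ** np.arange(order - 1, -1, -1)
    return codes @ powers


def label_rows(
    rows: np.ndarray,
    loci: Sequence[int],
    table: PenetranceTable,
    rng: np.random.Generator,
) -> np.ndarray:
    """Bernoulli case labels: P(case) = penetrance of each row's combo genotype."""
    idx = _combo_indices(np.atleast_2d(rows), loci, table.order)
    p = table.values[idx]
    return (rng.random(p.size) < p).astype(np.int8)


def label_row(
    row: np.ndarray,
    loci: Sequence[int],
    table: PenetranceTable,
    rng: np.random.Generator,
) -> int:
    """Label a single genotype row (see :func:`label_rows`)."""
    return int(label_rows(np.atleast_2d(row), loci, table, rng)[0])


def assemble_balanced(
    pool: SamplingPool,
    table: PenetranceTable,
    loci: Sequence[int],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> LabeledDataset:
    """Fill exact case and control quotas by rejection sampling.

    Candidate rows are generated and labeled in batches; overflow beyond a
    filled quota is discarded.  Output order: cases first, then controls,
    each in generation order.
    """
    n_cases, n_controls = config.n_cases, config.n_controls
    cap = QUOTA_ATTEMPT_FACTOR * (n_cases + n_controls)
    cases: list[np.ndarray] = []
    controls: list[np.ndarray] = []
    attempts = 0
    while len(cases) < n_cases or len(controls) < n_controls:
        if attempts >= cap:
            raise QuotaError(
                f"generated {attempts} candidates without filling quotas "
                f"({len(cases)}/{n_cases} cases, {len(controls)}/{n_controls} "
                "controls); the penetrance table makes one class too rare — "
                "adjust alpha, the target, or the quotas"
            )
        chunk = min(max(256, n_cases + n_controls), cap - attempts)
        rows = generate_rows(
            pool,
            chunk,
            rng,
            len_min=config.len_min,
            len_max=config.len_max,
            shared_breakpoints=config.shared_breakpoints,
        )
        labels = label_rows(rows, loci, table, rng)
        attempts += chunk
        for row, lab in zip(rows, labels):
            if lab and len(cases) < n_cases:
                cases.append(row)
            elif not lab and len(controls) < n_controls:
                controls.append(row)
    data = np.vstack(cases + controls)
    labels = np.concatenate(
        [np.ones(n_cases, dtype=np.int8), np.zeros(n_controls, dtype=np.int8)]
    )
    return LabeledDataset(
        genotypes=GenotypeMatrix(data=data, labels=labels),
        model_loci=np.asarray(loci, dtype=np.int64),
        table=table,
    )


def assemble_unbalanced(
    pool: SamplingPool,
    table: PenetranceTable,
    loci: Sequence[int],
    n_total: int,
    rng: np.random.Generator,
    len_min: int = 10,
    len_max: int = 30,
    shared_breakpoints: bool = False,
) -> LabeledDataset:
    """Label exactly n_total generated samples once, keeping natural proportions."""
    if n_total < 1:
        raise ModelError("n_total must be >= 1")
    rows = generate_rows(
        pool,
        n_total,
        rng,
        len_min=len_min,
        len_max=len_max,
        shared_breakpoints=shared_breakpoints,
    )
    labels = label_rows(rows, loci, table, rng)
    return LabeledDataset(
        genotypes=GenotypeMatrix(data=rows, labels=labels),
        model_loci=np.asarray(loci, dtype=np.int64),
        table=table,
    )


def replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    """Independent, individually reproducible stream for one replicate."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_REPLICATE_KEY, replicate))
    )


def run_simulation(
    config: SimulationConfig, sampling: GenotypeMatrix | None = None
) -> SimulationResult:
    """Run the full pipeline: pool, locus matching, model solving, datasets.

    Stages draw from independent sub-streams of ``config.seed``, so each
    replicate dataset is reproducible on its own.  The combination-genotype
    frequencies used when solving for f come from the *actual* pool MAFs at
    the matched loci, not the requested targets.  When ``config.output_dir``
    is set, every dataset is written along with the finalized model file.
    """
    if sampling is None:
        if config.sampling_path is None:
            raise ModelError("run_simulation needs a sampling matrix or sampling_path")
        sampling = load_sampling_dataset(config.sampling_path, config.labels_path)

    logger.info("stage 1/3: building the sampling pool (%d SNPs)", config.n_snps)
    pool_rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(_POOL_KEY,))
    )
    try:
        pool = build_pool(sampling, config.n_snps, pool_rng)
    except Exception as exc:
        raise type(exc)(f"[pool stage] {exc}") from None

    logger.info("stage 2/3: locus matching and model solving")
    match_rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(_MATCH_KEY,))
    )
    try:
        spec = (
            models.parse_model_file(config.model_path)
            if config.model_path is not None
            else models.canonical_spec(config.model_type, config.order)
        )
        if spec.order != len(config.mafs):
            raise ModelError(
                f"model order {spec.order} does not match {len(config.mafs)} MAFs"
            )
        loci = match_loci_by_maf(pool, config.mafs, match_rng)
        loci_mafs = pool.column_mafs[loci]
        if config.target_mode == "prevalence":
            f = models.solve_f_given_prevalence(
                spec, config.alpha, config.target_value, loci_mafs
            )
        else:
            f = models.solve_f_given_heritability(
                spec, config.alpha, config.target_value, loci_mafs
            )
        table = models.build_table(
            spec, config.alpha, f, loci_mafs, normalize_mode=config.normalize_mode
        )
    except Exception as exc:
        raise type(exc)(f"[model stage] {exc}") from None
    summary = table.summary()
    logger.info(
        "model solved: f=%.6g, achieved prevalence=%.6g, h2=%.6g%s",
        f,
        summary.prevalence,
        summary.heritability,
        " (table rescaled)" if table.normalized else "",
    )

    logger.info("stage 3/3: generating %d labeled dataset(s)", config.n_datasets)
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    datasets: list[LabeledDataset] = []
    paths: list[Path] = []
    for i in range(config.n_datasets):
        rng = replicate_rng(config.seed, i)
        try:
            if config.balanced:
                ds = assemble_balanced(pool, table, loci, config, rng)
            else:
                ds = assemble_unbalanced(
                    pool,
                    table,
                    loci,
                    config.n_total,
                    rng,
                    len_min=config.len_min,
                    len_max=config.len_max,
                    shared_breakpoints=config.shared_breakpoints,
                )
        except Exception as exc:
            raise type(exc)(f"[labeling stage, replicate {i + 1}] {exc}") from None
        datasets.append(ds)
        if out_dir is not None:
            path = out_dir / f"dataset_{i + 1}.csv"
            write_dataset(ds, path, config=config, seed=config.seed)
            paths.append(path)
    if out_dir is not None:
        model_path = out_dir / "model.csv"
        models.write_model_file(
            table,
            model_path,
            target_mode=config.target_mode,
            target_value=config.target_value,
            loci=loci,
            seed=config.seed,
        )
        paths.append(model_path)
    return SimulationResult(
        datasets=datasets,
        table=table,
        model_loci=loci,
        achieved_prevalence=summary.prevalence,
        achieved_heritability=summary.heritability,
        config=config,
        output_paths=paths,
    )


def write_dataset(
    dataset: LabeledDataset,
    path: str | Path,
    config: SimulationConfig | None = None,
    seed: int | None = None,
) -> None:
    """Write one dataset plus a ``.meta.json`` sidecar.

    The sidecar records the 0-based model locus columns, the penetrance table
    with its achieved prevalence/heritability, the seed and a config echo.
    """
    path = Path(path)
    write_genotype_matrix(dataset.genotypes, path)
    summary = dataset.table.summary()
    meta = {
        "model_loci": dataset.model_loci,
        "order": dataset.table.order,
        "alpha": dataset.table.alpha,
        "f": dataset.table.f,
        "mafs": dataset.table.mafs,
        "penetrance_table": dict(
            zip(dataset.table.labels, dataset.table.values.tolist())
        ),
        "normalized": dataset.table.normalized,
        "achieved_prevalence": summary.prevalence,
        "achieved_heritability": summary.heritability,
        "seed": seed,
        "config": dataclasses.asdict(config) if config is not None else None,
    }
    write_json_metadata(meta, path.with_suffix(path.suffix + ".meta.json"))
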