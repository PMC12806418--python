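"""Fragment resampling of SNP genotype data.

Simulated individuals are spliced together from column-aligned genotype
fragments of real (or synthetic) control samples.  The SNP axis is cut into
contiguous segments of random length; each segment of a simulated sample is
copied from a donor control chosen uniformly at random.  Because every
simulated genotype is an actual pool genotype at the same column, per-column
minor-allele frequencies are preserved in expectation, and linkage
disequilibrium is preserved within segments.

Genotype codes follow the 1/2/3 convention: 1 = homozygous common (AA),
2 = heterozygous (Aa), 3 = homozygous minor (aa).  Labels are 0 = control,
1 = case.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .exceptions import InfeasibleTargetsError, ModelError

__all__ = [
    "GenotypeMatrix",
    "SamplingPool",
    "SegmentPlan",
    "compute_maf",
    "column_mafs",
    "build_pool",
    "match_loci_by_maf",
    "draw_segment_plan",
    "resample_row",
    "generate_rows",
]

logger = logging.getLogger(__name__)

_VALID_CODES = frozenset({1, 2, 3})


@dataclass
class GenotypeMatrix:
    """Samples x SNPs matrix of genotype codes 1/2/3 with optional labels."""

    data: np.ndarray
    labels: np.ndarray | None = None
    snp_ids: list[str] | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ModelError(f"genotype matrix must be 2-D, got {self.data.ndim}-D")
        bad = ~np.isin(self.data, (1, 2, 3))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ModelError(
                f"invalid genotype code {self.data[i, j]} at row {i}, column {j}; "
                "codes must be 1, 2 or 3"
            )
        self.data = self.data.astype(np.int8, copy=False)
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (self.n_samples,):
                raise ModelError(
                    f"labels must have length {self.n_samples}, "
                    f"got shape {self.labels.shape}"
                )
            if not np.isin(self.labels, (0, 1)).all():
                raise ModelError("labels must be 0 (control) or 1 (case)")
            self.labels = self.labels.astype(np.int8, copy=False)
        if self.snp_ids is not None and len(self.snp_ids) != self.n_snps:
            raise ModelError("snp_ids length does not match the number of columns")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_snps(self) -> int:
        return self.data.shape[1]


@dataclass
class SamplingPool:
    """Control-only genotype matrix restricted to the simulated SNP columns."""

    data: np.ndarray
    column_mafs: np.ndarray
    flipped: np.ndarray
    source_columns: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.source_columns is None:
            self.source_columns = np.arange(self.n_snps)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_snps(self) -> int:
        return self.data.shape[1]


def compute_maf(column: Sequence[int]) -> float:
    """Minor-allele frequency of one genotype column.

    Each code carries (code - 1) copies of the minor allele; the frequency is
    folded onto [0, 0.5] when the coded allele is actually the major one.
    """
    maf, _ = _maf_and_flip(np.asarray(column))
    return maf


def _maf_and_flip(column: np.ndarray) -> tuple[float, bool]:
    if column.size == 0:
        raise ModelError("cannot compute MAF of an empty column")
    freq = float((column - 1).sum()) / (2 * column.size)
    if freq > 0.5:
        return 1.0 - freq, True
    return freq, False


def column_mafs(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-column MAFs and the mask of folded (flipped) columns."""
    data = np.asarray(data)
    if data.shape[0] == 0:
        raise ModelError("cannot compute MAFs of an empty matrix")
    freq = (data - 1).sum(axis=0) / (2.0 * data.shape[0])
    flipped = freq > 0.5
    return np.where(flipped, 1.0 - freq, freq), flipped


def build_pool(
    matrix: GenotypeMatrix, n_snps: int, rng: np.random.Generator
) -> SamplingPool:
    """Restrict to control rows and a uniform random subset of SNP columns.

    The selected columns keep their original left-to-right order, so genomic
    adjacency (and any LD structure) survives the subsetting.
    """
    if matrix.labels is None:
        raise ModelError("sampling dataset has no labels; cannot select controls")
    controls = matrix.data[matrix.labels == 0]
    if controls.shape[0] == 0:
        raise ModelError("sampling dataset contains no control samples")
    if n_snps > matrix.n_snps:
        raise ModelError(
            f"requested {n_snps} SNPs but the sampling dataset has {matrix.n_snps}"
        )
    cols = np.sort(rng.choice(matrix.n_snps, size=n_snps, replace=False))
    data = controls[:, cols]
    mafs, flipped = column_mafs(data)
    return SamplingPool(
        data=data, column_mafs=mafs, flipped=flipped, source_columns=cols
    )


def match_loci_by_maf(
    pool: SamplingPool,
    target_mafs: Sequence[float],
    rng: np.random.Generator,
    step: float = 0.01,
) -> np.ndarray:
    """Select K distinct pool columns whose MAFs match the targets.

    For each target, candidate columns are those with |MAF - target| <= w.
    The window starts at ``step`` and grows by ``step`` per round until every
    target can claim a distinct column; targets with fewer candidates claim
    first, each choosing uniformly among its unclaimed candidates.
    """
    targets = np.asarray(target_mafs, dtype=float)
    if np.any((targets <= 0) | (targets > 0.5)):
        raise InfeasibleTargetsError("target MAFs must lie in (0, 0.5]")
    k = targets.size
    if k > pool.n_snps:
        raise InfeasibleTargetsError(
            f"{k} model loci requested but the pool has only {pool.n_snps} columns"
        )
    w = step
    while w <= 0.5 + step:
        cands = [
            np.flatnonzero(np.abs(pool.column_mafs - t) <= w + 1e-12) for t in targets
        ]
        order = sorted(range(k), key=lambda i: len(cands[i]))
        claimed: set[int] = set()
        chosen = np.full(k, -1, dtype=np.int64)
        ok = True
        for i in order:
            avail = [c for c in cands[i] if c not in claimed]
            if not avail:
                ok = False
                break
            pick = int(rng.choice(avail))
            claimed.add(pick)
            chosen[i] = pick
        if ok:
            logger.debug("locus matching succeeded at window +/-%.2f", w)
            return chosen
        w += step
    raise InfeasibleTargetsError(
        f"could not match target MAFs {targets.tolist()} even with the search "
        "window expanded to the full [0, 0.5] range"
    )


@dataclass(frozen=True)
class SegmentPlan:
    """Partition of [0, n_snps) into contiguous fragments.

    ``breakpoints`` are the interior cut positions, strictly increasing.
    """

    n_snps: int
    breakpoints: np.ndarray

    def __post_init__(self):
        bp = np.asarray(self.breakpoints, dtype=np.int64)
        object.__setattr__(self, "breakpoints", bp)
        if self.n_snps < 1:
            raise ModelError("segment plan needs at least one column")
        if bp.size and (
            np.any(np.diff(bp) <= 0) or bp[0] <= 0 or bp[-1] >= self.n_snps
        ):
            raise ModelError("breakpoints must be strictly increasing interior cuts")

    @property
    def edges(self) -> np.ndarray:
        return np.concatenate(([0], self.breakpoints, [self.n_snps]))

    @property
    def lengths(self) -> np.ndarray:
        return np.diff(self.edges)

    @property
    def n_fragments(self) -> int:
        return self.breakpoints.size + 1

    def fragments(self) -> Iterator[tuple[int, int]]:
        edges = self.edges
        for a, b in zip(edges[:-1], edges[1:]):
            yield int(a), int(b)


def draw_segment_plan(
    n_snps: int, len_min: int, len_max: int, rng: np.random.Generator
) -> SegmentPlan:
    """Cut the SNP axis left to right into fragments of uniform random length.

    Lengths are drawn uniformly from [len_min, len_max]; the final fragment is
    truncated to whatever remains.
    """
    if n_snps < 1:
        raise ModelError("cannot draw a segment plan over zero columns")
    if not 1 <= len_min <= len_max:
        raise ModelError(
            f"segment-length bounds must satisfy 1 <= len_min <= len_max, "
            f"got [{len_min}, {len_max}]"
        )
    cuts = []
    pos = 0
    while pos < n_snps:
        pos += int(rng.integers(len_min, len_max + 1))
        if pos < n_snps:
            cuts.append(pos)
    return SegmentPlan(n_snps=n_snps, breakpoints=np.asarray(cuts, dtype=np.int64))


def resample_row(
    pool: SamplingPool, plan: SegmentPlan, rng: np.random.Generator
) -> np.ndarray:
    """Splice one simulated sample: a uniform random donor per fragment."""
    if plan.n_snps != pool.n_snps:
        raise ModelError(
            f"segment plan covers {plan.n_snps} columns but the pool has {pool.n_snps}"
        )
    donors = rng.integers(0, pool.n_samples, size=plan.n_fragments)
    donor_per_col = np.repeat(donors, plan.lengths)
    return pool.data[donor_per_col, np.arange(pool.n_snps)]


def generate_rows(
    pool: SamplingPool,
    n: int,
    rng: np.random.Generator,
    len_min: int = 10,
    len_max: int = 30,
    shared_breakpoints: bool = False,
) -> np.ndarray:
    """Generate n simulated samples by fragment resampling.

    By default a fresh segment plan is drawn per sample; with
    ``shared_breakpoints`` a single plan is drawn once and reused, so every
    simulated sample is cut at the same columns.
    """
    if n < 1:
        raise ModelError("must generate at least one row")
    out = np.empty((n, pool.n_snps), dtype=np.int8)
    plan = draw_segment_plan(pool.n_snps, len_min, len_max, rng) if shared_breakpoints else None
    for i in range(n):
        row_plan = plan if plan is not None else draw_segment_plan(
            pool.n_snps, len_min, len_max, rng
        )
        out[i] = resample_row(pool, row_plan, rng)
    return out
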