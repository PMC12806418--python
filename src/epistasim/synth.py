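"""Synthetic sampling pools with known minor-allele frequencies.

Real GWAS panels (e.g. a case-control SNP matrix) serve as the sampling pool
in production use.  This module fabricates pools with a controlled
statistical structure — per-SNP MAFs drawn from a chosen law, genotypes in
Hardy-Weinberg proportions, optional block-wise linkage disequilibrium, and
genotype-independent control/case labels — so the resampler and dataset
builder can be exercised and validated without any external data.

The LD model is deliberately simple: SNPs are grouped into fixed-size blocks
sharing one true MAF; per sample, each block draws a latent genotype, and
every column in the block copies it with probability equal to the requested
within-block correlation (drawing independently otherwise).  At correlation
1 all columns of a block are identical; at 0 they are independent.  This is
a test harness for LD *preservation*, not a population-genetic LD model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ModelError
from .resampling import GenotypeMatrix, column_mafs

__all__ = ["PoolRecipe", "SynthPool", "synth_pool", "hwe_check"]


@dataclass(frozen=True)
class PoolRecipe:
    """Recipe for a synthetic sampling pool.

    ``mafs`` gives explicit per-SNP (or, with LD, per-block) true MAFs;
    otherwise MAFs are drawn uniformly from [maf_low, maf_high].  With
    ``block_size`` > 0, columns are grouped into consecutive blocks of that
    size which share a true MAF and are correlated at
    ``within_block_correlation``.
    """

    n_samples: int
    n_snps: int
    maf_low: float = 0.05
    maf_high: float = 0.5
    mafs: tuple[float, ...] | None = None
    block_size: int = 0
    within_block_correlation: float = 0.0
    control_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1 or self.n_snps < 1:
            raise ModelError("pool recipe needs at least one sample and one SNP")
        if self.mafs is None and not 0.01 <= self.maf_low <= self.maf_high <= 0.5:
            raise ModelError(
                f"MAF range [{self.maf_low}, {self.maf_high}] must sit inside [0.01, 0.5]"
            )
        if self.block_size > self.n_snps:
            raise ModelError("block_size cannot exceed n_snps")
        if not 0.0 <= self.within_block_correlation <= 1.0:
            raise ModelError("within_block_correlation must lie in [0, 1]")
        if not 0.0 <= self.control_fraction <= 1.0:
            raise ModelError("control_fraction must lie in [0, 1]")


@dataclass
class SynthPool:
    """A synthesized pool plus the ground truth used to build it."""

    matrix: GenotypeMatrix
    true_mafs: np.ndarray
    block_map: np.ndarray | None = None


def _hwe_draw(mafs: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Map uniforms to genotype codes 1/2/3 via per-column HWE thresholds."""
    q_aa = (1.0 - mafs) ** 2
    q_het = 2.0 * mafs * (1.0 - mafs)
    return (1 + (u > q_aa).astype(np.int8) + (u > q_aa + q_het).astype(np.int8)).astype(
        np.int8
    )


def synth_pool(recipe: PoolRecipe) -> SynthPool:
    """Generate a genotype matrix according to the recipe (seed-deterministic).

    Genotypes follow Hardy-Weinberg proportions at each column's true MAF;
    labels are assigned by ``control_fraction`` independently of genotype, so
    the background carries no association signal.
    """
    rng = np.random.default_rng(recipe.seed)
    n, p = recipe.n_samples, recipe.n_snps
    if recipe.block_size > 0:
        n_blocks = -(-p // recipe.block_size)
        block_map = np.minimum(
            np.arange(p) // recipe.block_size, n_blocks - 1
        ).astype(np.int64)
        if recipe.mafs is not None:
            block_mafs = np.asarray(recipe.mafs, dtype=float)
            if block_mafs.size != n_blocks:
                raise ModelError(
                    f"explicit mafs must give one value per block ({n_blocks})"
                )
        else:
            block_mafs = rng.uniform(recipe.maf_low, recipe.maf_high, size=n_blocks)
        true_mafs = block_mafs[block_map]
        latent = _hwe_draw(
            block_mafs[np.newaxis, :], rng.random((n, n_blocks))
        )
        indep = _hwe_draw(true_mafs[np.newaxis, :], rng.random((n, p)))
        copy = rng.random((n, p)) < recipe.within_block_correlation
        data = np.where(copy, latent[:, block_map], indep)
    else:
        block_map = None
        if recipe.mafs is not None:
            true_mafs = np.asarray(recipe.mafs, dtype=float)
            if true_mafs.size != p:
                raise ModelError(f"explicit mafs must give one value per SNP ({p})")
        else:
            true_mafs = rng.uniform(recipe.maf_low, recipe.maf_high, size=p)
        data = _hwe_draw(true_mafs[np.newaxis, :], rng.random((n, p)))
    n_controls = int(round(recipe.control_fraction * n))
    labels = np.ones(n, dtype=np.int8)
    labels[rng.permutation(n)[:n_controls]] = 0
    matrix = GenotypeMatrix(data=data, labels=labels)
    return SynthPool(matrix=matrix, true_mafs=true_mafs, block_map=block_map)


def hwe_check(matrix: GenotypeMatrix | np.ndarray) -> pd.DataFrame:
    """Per-column 1-df chi-square test against Hardy-Weinberg proportions.

    Expected genotype counts come from each column's *estimated* MAF (hence
    one residual degree of freedom).  Monomorphic columns are skipped and
    flagged.  Returns a DataFrame with columns ``maf``, ``statistic``,
    ``pvalue``, ``skipped``.
    """
    data = matrix.data if isinstance(matrix, GenotypeMatrix) else np.asarray(matrix)
    if data.size == 0:
        raise ModelError("cannot run a HWE check on an empty matrix")
    n = data.shape[0]
    mafs, _ = column_mafs(data)
    counts = np.stack([(data == code).sum(axis=0) for code in (1, 2, 3)])
    expected = n * np.stack(
        [(1 - mafs) ** 2, 2 * mafs * (1 - mafs), mafs**2]
    )
    skipped = mafs == 0.0  # monomorphic after folding (all-1 or all-3 columns)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(
            skipped,
            np.nan,
            ((counts - expected) ** 2 / np.where(expected > 0, expected, 1.0)).sum(
                axis=0
            ),
        )
    pvalue = np.where(skipped, np.nan, stats.chi2.sf(stat, df=1))
    return pd.DataFrame(
        {"maf": mafs, "statistic": stat, "pvalue": pvalue, "skipped": skipped}
    )
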