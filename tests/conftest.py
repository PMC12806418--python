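import itertools

import numpy as np
import pytest

import epistasim as ep


# ---------------------------------------------------------------------------
# Independent brute-force oracles: plain nested loops over all 3^K genotypes,
# sharing no code with the vectorized implementation they check.
# ---------------------------------------------------------------------------

def naive_combo_weights(mafs):
    """Enumerate every combination genotype and its frequency, first locus
    most significant."""
    out = []
    for codes in itertools.product(range(3), repeat=len(mafs)):
        q = 1.0
        for c, m in zip(codes, mafs):
            q *= [(1 - m) ** 2, 2 * m * (1 - m), m * m][c]
        out.append((codes, q))
    return out


def naive_prevalence(values, mafs):
    return sum(v * q for v, (_, q) in zip(values, naive_combo_weights(mafs)))


def naive_heritability(values, mafs):
    p_bar = naive_prevalence(values, mafs)
    var = sum(
        (v - p_bar) ** 2 * q for v, (_, q) in zip(values, naive_combo_weights(mafs))
    )
    return var / (p_bar * (1 - p_bar))


@pytest.fixture(scope="session")
def small_pool():
    """Synthetic 400-sample, 120-SNP all-control pool (HWE, no LD)."""
    result = ep.synth_pool(
        ep.PoolRecipe(n_samples=400, n_snps=120, maf_low=0.05, maf_high=0.5, seed=42)
    )
    rng = np.random.default_rng(0)
    return ep.build_pool(result.matrix, 120, rng)


@pytest.fixture(scope="session")
def table1():
    """Two-locus threshold table with cells 0.084 / 0.210 at MAFs 0.5."""
    spec = ep.canonical_spec("threshold", 2)
    return ep.build_table(spec, 0.084, 2.5, [0.5, 0.5])
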