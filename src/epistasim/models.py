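"""Epistasis penetrance models: construction, population summaries, inversion.

A K-order epistasis model with marginal effects assigns each of the 3^K
combination genotypes a penetrance P(D|g) expressed as a formula in the
baseline penetrance alpha (variable ``x``) and the relative penetrance f
(variable ``y``).  Under Hardy-Weinberg equilibrium at each locus and linkage
equilibrium between loci, the genotype frequencies follow from the per-locus
minor-allele frequencies, and the model induces a population prevalence

    P(D) = sum_i P(D|g_i) P(g_i)

and a (broad-sense, attributable) heritability

    h^2 = sum_i (P(D|g_i) - P(D))^2 P(g_i) / (P(D) (1 - P(D))).

Given alpha, the MAFs and a target prevalence *or* heritability, the relative
penetrance f is recovered by one-dimensional root finding.  If the solved
table contains cells above 1 it is rescaled by S(p) = p / (1 + M) with M the
maximum cell (``normalize_mode="max"`` divides by M instead), and the
achieved prevalence/heritability of the finalized table are recomputed.

Cell ordering is the base-3 enumeration of minor-allele counts with the first
locus most significant; code 0 is the homozygous common genotype.  Labels use
one letter pair per locus, e.g. ``AaBb`` for K=2.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .exceptions import ExpressionError, FormatError, ModelError, NoSolutionError
from .expressions import PenetranceExpression

__all__ = [
    "GenotypeFrequencyTriple",
    "EMEModelSpec",
    "PenetranceTable",
    "PopulationSummary",
    "genotype_frequencies",
    "combo_codes",
    "combo_index",
    "genotype_label",
    "parse_genotype_label",
    "combo_frequency",
    "all_combo_frequencies",
    "build_table",
    "normalize_table",
    "prevalence",
    "heritability",
    "solve_f_given_prevalence",
    "solve_f_given_heritability",
    "parse_model_file",
    "canonical_spec",
    "write_model_file",
    "CANONICAL_MODEL_TYPES",
]

logger = logging.getLogger(__name__)

#: Upper cap on the relative penetrance explored by the solvers.
F_CAP = float(2**40)

CANONICAL_MODEL_TYPES = ("additive", "multiplicative", "threshold")


@dataclass(frozen=True)
class GenotypeFrequencyTriple:
    """Hardy-Weinberg genotype frequencies (AA, Aa, aa) at one SNP."""

    q_AA: float
    q_Aa: float
    q_aa: float

    def as_array(self) -> np.ndarray:
        return np.array([self.q_AA, self.q_Aa, self.q_aa])


@dataclass(frozen=True)
class PopulationSummary:
    """Population-level summary of a finalized penetrance table."""

    prevalence: float
    heritability: float


def genotype_frequencies(maf: float) -> GenotypeFrequencyTriple:
    """Hardy-Weinberg genotype frequencies ((1-m)^2, 2m(1-m), m^2).

    Parameters
    ----------
    maf : float
        Minor-allele frequency, in [0, 0.5].
    """
    m = float(maf)
    if not 0.0 <= m <= 0.5:
        raise ModelError(f"MAF must lie in [0, 0.5], got {maf}")
    return GenotypeFrequencyTriple((1 - m) ** 2, 2 * m * (1 - m), m * m)


def combo_codes(index: int, order: int) -> tuple[int, ...]:
    """Decode a cell index into per-locus minor-allele counts (base 3).

    The first locus is most significant: for K=2, index 5 -> (1, 2).
    """
    if not 0 <= index < 3**order:
        raise ModelError(f"combo index {index} out of range for order {order}")
    codes = []
    for k in range(order - 1, -1, -1):
        codes.append((index // 3**k) % 3)
    return tuple(codes)


def combo_index(codes: Sequence[int]) -> int:
    """Encode per-locus minor-allele counts into the base-3 cell index."""
    idx = 0
    for c in codes:
        if c not in (0, 1, 2):
            raise ModelError(f"genotype code must be 0, 1 or 2, got {c}")
        idx = idx * 3 + int(c)
    return idx


_PAIRS = ("{u}{u}", "{u}{l}", "{l}{l}")


def genotype_label(codes: Sequence[int]) -> str:
    """Label a combination genotype, one letter pair per locus (``AaBb``...)."""
    parts = []
    for k, c in enumerate(codes):
        letter = chr(ord("A") + k)
        parts.append(_PAIRS[c].format(u=letter, l=letter.lower()))
    return "".join(parts)


def parse_genotype_label(label: str) -> tuple[int, ...]:
    """Invert :func:`genotype_label`; raises FormatError on malformed labels."""
    label = label.strip()
    if len(label) % 2 or not label:
        raise FormatError(f"genotype label {label!r} must be letter pairs")
    codes = []
    for k in range(len(label) // 2):
        a, b = label[2 * k], label[2 * k + 1]
        letter = chr(ord("A") + k)
        pair = (a + b)
        if pair == letter + letter:
            codes.append(0)
        elif pair == letter + letter.lower():
            codes.append(1)
        elif pair == letter.lower() + letter.lower():
            codes.append(2)
        else:
            raise FormatError(
                f"genotype label {label!r}: locus {k + 1} must be one of "
                f"{letter}{letter}/{letter}{letter.lower()}/{letter.lower()}{letter.lower()}"
            )
    return tuple(codes)


def combo_frequency(codes: Sequence[int], mafs: Sequence[float]) -> float:
    """Frequency of one combination genotype under linkage equilibrium.

    The product over loci of the Hardy-Weinberg genotype frequency selected
    by each minor-allele count.
    """
    if len(codes) != len(mafs):
        raise ModelError(
            f"combo has {len(codes)} loci but {len(mafs)} MAFs were given"
        )
    p = 1.0
    for c, m in zip(codes, mafs):
        p *= genotype_frequencies(m).as_array()[c]
    return p


def all_combo_frequencies(mafs: Sequence[float]) -> np.ndarray:
    """Frequencies of all 3^K combination genotypes, in cell-index order."""
    weights = np.ones(1)
    for m in mafs:
        weights = np.multiply.outer(weights, genotype_frequencies(m).as_array()).ravel()
    return weights


@dataclass(frozen=True)
class EMEModelSpec:
    """Symbolic K-order epistasis model with marginal effects.

    One penetrance expression per combination genotype, stored in canonical
    cell-index order.  ``labels[i]`` is the genotype label of cell ``i``.
    """

    order: int
    labels: tuple[str, ...]
    expressions: tuple[PenetranceExpression, ...]

    def __post_init__(self):
        if self.order < 1:
            raise ModelError(f"model order must be >= 1, got {self.order}")
        n = 3**self.order
        if len(self.expressions) != n or len(self.labels) != n:
            raise ModelError(
                f"a {self.order}-order model needs {n} cells, got "
                f"{len(self.expressions)}"
            )
        if len(set(self.labels)) != n:
            raise ModelError("duplicate genotype labels in model")

    def evaluate(self, alpha: float, f: float) -> np.ndarray:
        """Raw cell values F(alpha, f), before any normalization.

        Raises ModelError naming the offending cell if a value is negative
        or non-finite.
        """
        out = np.empty(3**self.order)
        for i, expr in enumerate(self.expressions):
            v = expr(alpha, f)
            if not np.isfinite(v) or v < 0:
                raise ModelError(
                    f"cell {self.labels[i]} ({expr.text!r}) evaluates to {v} "
                    f"at alpha={alpha}, f={f}"
                )
            out[i] = v
        return out


@dataclass(frozen=True)
class PenetranceTable:
    """Finalized penetrance table of a K-order model.

    ``values`` are the final cell penetrances (all in [0, 1]); ``raw_values``
    are the expression values before rescaling, kept so that the population
    equations the table was solved against remain inspectable.
    """

    order: int
    values: np.ndarray
    mafs: np.ndarray
    alpha: float
    f: float
    normalized: bool = False
    normalize_mode: str = "one_plus_max"
    raw_values: np.ndarray = field(default=None)  # type: ignore[assignment]
    labels: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        mafs = np.asarray(self.mafs, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "mafs", mafs)
        if values.shape != (3**self.order,):
            raise ModelError(
                f"table for order {self.order} needs {3**self.order} values, "
                f"got shape {values.shape}"
            )
        if mafs.shape != (self.order,):
            raise ModelError(f"need {self.order} MAFs, got shape {mafs.shape}")
        if np.any((mafs < 0) | (mafs > 0.5)):
            raise ModelError("MAFs must lie in [0, 0.5]")
        if np.any(~np.isfinite(values)) or np.any(values < 0) or np.any(values > 1):
            raise ModelError("finalized penetrance values must lie in [0, 1]")
        if self.raw_values is None:
            object.__setattr__(self, "raw_values", values.copy())
        else:
            object.__setattr__(
                self, "raw_values", np.asarray(self.raw_values, dtype=float)
            )
        if self.labels is None:
            object.__setattr__(
                self,
                "labels",
                tuple(
                    genotype_label(combo_codes(i, self.order))
                    for i in range(3**self.order)
                ),
            )

    def combo_frequencies(self) -> np.ndarray:
        return all_combo_frequencies(self.mafs)

    def summary(self) -> PopulationSummary:
        """Achieved prevalence and heritability of the finalized table."""
        return PopulationSummary(prevalence(self), heritability(self))


def normalize_table(values: np.ndarray, mode: str = "one_plus_max") -> np.ndarray:
    """Rescale a penetrance vector so every cell lies in [0, 1].

    With ``mode="one_plus_max"`` each value is divided by 1 + M, M being the
    maximum input value; ``mode="max"`` divides by M (pinning the maximum to
    exactly 1).  Inputs already within [0, 1] are returned unchanged.  The
    map is monotone, so the cell ranking is preserved.
    """
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ModelError("cannot normalize a table with negative penetrances")
    m = float(values.max())
    if m <= 1.0:
        return values.copy()
    if mode == "one_plus_max":
        return values / (1.0 + m)
    if mode == "max":
        return values / m
    raise ModelError(f"unknown normalize_mode {mode!r}")


def build_table(
    spec: EMEModelSpec,
    alpha: float,
    f: float,
    mafs: Sequence[float],
    normalize_mode: str = "one_plus_max",
) -> PenetranceTable:
    """Evaluate a model spec at (alpha, f) and finalize the penetrance table.

    Cells exceeding 1 trigger rescaling (see :func:`normalize_table`); the
    ``normalized`` flag records whether that happened.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ModelError(f"alpha must lie in [0, 1], got {alpha}")
    if f < 0:
        raise ModelError(f"relative penetrance f must be non-negative, got {f}")
    raw = spec.evaluate(alpha, f)
    values = normalize_table(raw, normalize_mode)
    return PenetranceTable(
        order=spec.order,
        values=values,
        mafs=np.asarray(mafs, dtype=float),
        alpha=float(alpha),
        f=float(f),
        normalized=bool(raw.max() > 1.0),
        normalize_mode=normalize_mode,
        raw_values=raw,
        labels=spec.labels,
    )


def prevalence(table: PenetranceTable) -> float:
    """Population prevalence: penetrances averaged over genotype frequencies."""
    return float(table.values @ table.combo_frequencies())


def heritability(table: PenetranceTable) -> float:
    """Variance in liability attributable to the modeled loci.

    The between-genotype variance of penetrance divided by the Bernoulli
    phenotype variance P(D)(1 - P(D)); undefined when the prevalence is 0
    or 1.
    """
    w = table.combo_frequencies()
    p_bar = float(table.values @ w)
    if not 0.0 < p_bar < 1.0:
        raise ModelError(
            f"heritability undefined: prevalence is {p_bar} (must be in (0, 1))"
        )
    var = float(((table.values - p_bar) ** 2) @ w)
    return var / (p_bar * (1.0 - p_bar))


# ---------------------------------------------------------------------------
# Inverse solving for the relative penetrance f
# ---------------------------------------------------------------------------

def _raw_prevalence(spec, alpha, f, weights) -> float:
    return float(spec.evaluate(alpha, f) @ weights)


def _raw_heritability(spec, alpha, f, weights) -> float | None:
    """h^2 of the raw table; None where the raw prevalence leaves (0, 1)."""
    vals = spec.evaluate(alpha, f)
    p_bar = float(vals @ weights)
    if not 0.0 < p_bar < 1.0:
        return None
    return float(((vals - p_bar) ** 2) @ weights) / (p_bar * (1.0 - p_bar))


def _first_sign_change_root(g, grid: np.ndarray, vals: np.ndarray) -> float:
    """Root in the first sign-change interval of g along the grid."""
    sign = np.sign(vals)
    changes = np.flatnonzero(sign[:-1] * sign[1:] < 0)
    exact = np.flatnonzero(sign == 0)
    if exact.size and (not changes.size or exact[0] <= changes[0]):
        return float(grid[exact[0]])
    if not changes.size:
        raise NoSolutionError("no sign change located in the bracket")
    j = changes[0]
    if changes.size > 1:
        warnings.warn(
            "objective has multiple roots in f; returning the smallest",
            stacklevel=3,
        )
    return float(brentq(g, grid[j], grid[j + 1], xtol=1e-12))


def solve_f_given_prevalence(
    spec: EMEModelSpec,
    alpha: float,
    target_prevalence: float,
    mafs: Sequence[float],
    tol: float = 1e-10,
) -> float:
    """Relative penetrance f whose model prevalence equals the target.

    The objective is the prevalence of the raw (pre-rescaling) table; the
    bracket [0, f_hi] is grown by doubling f_hi until the target is crossed,
    then refined by bisection.  For specs that are not monotone in f the
    smallest root is returned with a warning.

    Raises
    ------
    NoSolutionError
        If no f in [0, 2^40] attains the target.
    """
    if not 0.0 < target_prevalence < 1.0:
        raise ModelError(f"target prevalence must lie in (0, 1), got {target_prevalence}")
    if not 0.0 < alpha < 1.0:
        raise ModelError(f"alpha must lie in (0, 1), got {alpha}")
    weights = all_combo_frequencies(mafs)

    def g(f: float) -> float:
        return _raw_prevalence(spec, alpha, f, weights) - target_prevalence

    g0 = g(0.0)
    if abs(g0) <= tol:
        return 0.0
    f_hi = 2.0
    while g(f_hi) * g0 > 0:
        f_hi *= 2.0
        if f_hi > F_CAP:
            raise NoSolutionError(
                f"prevalence {target_prevalence} unreachable for any f in "
                f"[0, {F_CAP:.0f}] (alpha={alpha})"
            )
    grid = np.linspace(0.0, f_hi, 257)
    vals = np.array([g(x) for x in grid])
    diffs = np.diff(vals)
    if np.any(diffs < -tol) and np.any(diffs > tol):
        logger.warning(
            "prevalence is not monotone in f for this model; smallest root returned"
        )
    root = _first_sign_change_root(g, grid, vals)
    if abs(g(root)) > max(tol, 1e-8 * target_prevalence):
        raise NoSolutionError("bisection failed to meet the prevalence tolerance")
    return root


def solve_f_given_heritability(
    spec: EMEModelSpec,
    alpha: float,
    target_h2: float,
    mafs: Sequence[float],
    tol: float = 1e-10,
    grid_factor: float = 1.05,
) -> float:
    """Relative penetrance f whose model heritability equals the target.

    h^2(f) is scanned on a multiplicative grid starting at the null point
    f = 1 (where every canonical model is constant and h^2 = 0) and moving
    toward larger relative risk; the first crossing of the target is refined
    by bisection.  If h^2 already exceeds the target at f = 1, the scan runs
    downward instead.  The scan stops where the raw prevalence leaves (0, 1),
    beyond which the heritability equation is undefined.

    Raises
    ------
    NoSolutionError
        If the target is never crossed before the scan cap.
    """
    if not 0.0 < target_h2 < 1.0:
        raise ModelError(f"target heritability must lie in (0, 1), got {target_h2}")
    if not 0.0 < alpha < 1.0:
        raise ModelError(f"alpha must lie in (0, 1), got {alpha}")
    weights = all_combo_frequencies(mafs)

    def h(f: float) -> float | None:
        return _raw_heritability(spec, alpha, f, weights)

    h1 = h(1.0)
    if h1 is None:
        raise NoSolutionError("raw prevalence outside (0, 1) at f = 1")
    upward = h1 < target_h2
    factor = grid_factor if upward else 1.0 / grid_factor
    f_lo_cap = 1e-9

    def objective(f: float) -> float:
        v = h(f)
        if v is None:
            raise NoSolutionError(
                "raw prevalence left (0, 1) while solving for heritability"
            )
        return v - target_h2

    f_prev, g_prev = 1.0, h1 - target_h2
    f_cur = 1.0
    brackets: list[tuple[float, float]] = []
    while (upward and f_cur < F_CAP) or (not upward and f_cur > f_lo_cap):
        f_cur = f_cur * factor
        h_cur = h(f_cur)
        if h_cur is None:
            break
        g_cur = h_cur - target_h2
        if g_prev * g_cur <= 0:
            brackets.append((min(f_prev, f_cur), max(f_prev, f_cur)))
        f_prev, g_prev = f_cur, g_cur
    if not brackets:
        raise NoSolutionError(
            f"heritability {target_h2} not attained by any f in the scanned "
            f"range (alpha={alpha})"
        )
    if len(brackets) > 1:
        warnings.warn(
            "heritability objective crosses the target more than once; "
            "returning the root nearest f = 1",
            stacklevel=2,
        )
    lo, hi = brackets[0]
    root = float(brentq(objective, lo, hi, xtol=1e-12))
    if abs(objective(root)) > max(tol, 1e-8 * target_h2):
        raise NoSolutionError("bisection failed to meet the heritability tolerance")
    return root


# ---------------------------------------------------------------------------
# Model files and canonical model families
# ---------------------------------------------------------------------------

def parse_model_file(path: str | Path) -> EMEModelSpec:
    """Read a model file: CSV with columns ``genotype,expression``.

    One row per combination genotype; the order K is inferred from the label
    length (one letter pair per locus) and exactly 3^K rows are required.
    Rows may appear in any order; they are sorted into canonical cell order.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", skipinitialspace=True, dtype=str)
    except Exception as exc:
        raise FormatError(f"cannot read model file {path}: {exc}") from None
    cols = {c.strip().lower(): c for c in df.columns}
    if "genotype" in cols and "expression" in cols:
        geno_col, expr_col = cols["genotype"], cols["expression"]
    elif len(df.columns) == 2:
        geno_col, expr_col = df.columns
    else:
        raise FormatError(
            f"model file {path} must have columns 'genotype' and 'expression'"
        )
    rows = list(zip(df[geno_col].astype(str), df[expr_col].astype(str)))
    if not rows:
        raise FormatError(f"model file {path} has no rows")
    order = len(rows[0][0].strip()) // 2
    if order < 1:
        raise FormatError(f"model file {path}: cannot infer order from row 1")
    if len(rows) != 3**order:
        raise FormatError(
            f"model file {path}: inferred order {order} needs {3 ** order} rows, "
            f"found {len(rows)}"
        )
    cells: dict[int, tuple[str, PenetranceExpression]] = {}
    for r, (label, text) in enumerate(rows, start=2):
        codes = parse_genotype_label(label)
        if len(codes) != order:
            raise FormatError(
                f"model file {path} row {r}: label {label!r} has "
                f"{len(codes)} loci, expected {order}"
            )
        idx = combo_index(codes)
        if idx in cells:
            raise FormatError(
                f"model file {path} row {r}: duplicate genotype {label!r}"
            )
        try:
            expr = PenetranceExpression(text)
        except ExpressionError as exc:
            raise FormatError(f"model file {path} row {r}: {exc}") from None
        cells[idx] = (genotype_label(codes), expr)
    labels, exprs = zip(*(cells[i] for i in range(3**order)))
    return EMEModelSpec(order=order, labels=labels, expressions=exprs)


def canonical_spec(model_type: str, order: int) -> EMEModelSpec:
    """One of the three canonical model families at a given order.

    With s = total minor-allele count of the combination genotype:

    - ``additive``:        x * (1 + s*y)
    - ``multiplicative``:  x * y^s
    - ``threshold``:       x where any locus is homozygous common, else x*y
    """
    if order < 1:
        raise ModelError(f"model order must be >= 1, got {order}")
    if model_type not in CANONICAL_MODEL_TYPES:
        raise ModelError(
            f"unknown model type {model_type!r}; choose from {CANONICAL_MODEL_TYPES}"
        )
    labels, exprs = [], []
    for codes in itertools.product((0, 1, 2), repeat=order):
        labels.append(genotype_label(codes))
        s = sum(codes)
        if model_type == "additive":
            text = "x" if s == 0 else f"x*(1+{s}*y)"
        elif model_type == "multiplicative":
            text = "x" if s == 0 else f"x*y^{s}"
        else:  # threshold
            text = "x" if 0 in codes else "x*y"
        exprs.append(PenetranceExpression(text))
    return EMEModelSpec(order=order, labels=tuple(labels), expressions=tuple(exprs))


def write_model_file(
    table: PenetranceTable,
    path: str | Path,
    *,
    target_mode: str | None = None,
    target_value: float | None = None,
    loci: Iterable[int] | None = None,
    seed: int | None = None,
) -> None:
    """Write a finalized table: ``genotype,penetrance`` CSV with metadata.

    The comment block records K, alpha, f, the requested target, the achieved
    prevalence and heritability of the finalized table, the selected locus
    column indices (0-based) and whether rescaling was applied.
    """
    path = Path(path)
    summary = table.summary()
    lines = [
        f"# order: {table.order}",
        f"# alpha: {table.alpha!r}",
        f"# f: {table.f!r}",
        f"# mafs: {','.join(repr(float(m)) for m in table.mafs)}",
    ]
    if target_mode is not None:
        lines.append(f"# requested_{target_mode}: {target_value!r}")
    lines += [
        f"# achieved_prevalence: {summary.prevalence!r}",
        f"# achieved_heritability: {summary.heritability!r}",
        f"# normalized: {table.normalized}",
        f"# normalize_mode: {table.normalize_mode}",
    ]
    if loci is not None:
        lines.append(f"# model_loci: {','.join(str(int(j)) for j in loci)}")
    if seed is not None:
        lines.append(f"# seed: {seed}")
    lines.append("genotype,penetrance")
    for label, value in zip(table.labels, table.values):
        lines.append(f"{label},{float(value)!r}")
    path.write_text("\n".join(lines) + "\n")
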