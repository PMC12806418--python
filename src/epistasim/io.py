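"""Reading and writing delimited genotype matrices.

Dialect: comma- or tab-separated integers (auto-detected), one row per
sample, one column per SNP, codes 1/2/3.  Labels (0 = control, 1 = case) sit
either in a final column named ``label``/``class`` (header required) or in a
companion single-column file.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .exceptions import FormatError, ModelError
from .resampling import GenotypeMatrix

__all__ = ["load_sampling_dataset", "write_genotype_matrix"]

_LABEL_NAMES = {"label", "class"}


def _sniff(path: Path) -> tuple[str, bool]:
    """Return (delimiter, has_header) from the first line."""
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise FormatError(f"{path} is empty")
    delim = "\t" if first.count("\t") >= first.count(",") and "\t" in first else ","
    tokens = [t.strip() for t in first.rstrip("\n").split(delim)]

    def numeric(t: str) -> bool:
        try:
            float(t)
            return True
        except ValueError:
            return False

    return delim, not all(numeric(t) for t in tokens if t)


def load_sampling_dataset(
    path: str | Path, labels_path: str | Path | None = None
) -> GenotypeMatrix:
    """Load a sampling SNP dataset into a :class:`GenotypeMatrix`.

    Labels are taken from a ``label``/``class`` column when present, else
    from ``labels_path`` (one 0/1 per line) when given; otherwise the matrix
    is unlabeled.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"sampling dataset {path} does not exist")
    delim, has_header = _sniff(path)
    df = pd.read_csv(
        path, sep=delim, header=0 if has_header else None, comment="#"
    )
    labels = None
    snp_ids = None
    if has_header:
        label_col = next(
            (c for c in df.columns if str(c).strip().lower() in _LABEL_NAMES), None
        )
        if label_col is not None:
            labels = df[label_col].to_numpy()
            df = df.drop(columns=[label_col])
        snp_ids = [str(c) for c in df.columns]
    data = df.to_numpy()
    if not np.issubdtype(data.dtype, np.number):
        raise FormatError(f"{path} contains non-numeric genotype entries")
    bad = ~np.isin(data, (1, 2, 3))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FormatError(
            f"{path}: invalid genotype code {data[i, j]} at row {i}, column {j}"
        )
    if labels_path is not None:
        if labels is not None:
            raise FormatError(
                f"{path} already has a label column; companion labels file "
                f"{labels_path} conflicts"
            )
        labels = np.loadtxt(labels_path, dtype=int, ndmin=1)
    try:
        return GenotypeMatrix(data=data, labels=labels, snp_ids=snp_ids)
    except ModelError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_genotype_matrix(
    matrix: GenotypeMatrix, path: str | Path, delimiter: str = ","
) -> None:
    """Write a genotype matrix; labels, when present, go in a final ``label`` column."""
    path = Path(path)
    ids = matrix.snp_ids or [f"snp{j}" for j in range(matrix.n_snps)]
    df = pd.DataFrame(matrix.data, columns=ids)
    if matrix.labels is not None:
        df["label"] = matrix.labels
    df.to_csv(path, sep=delimiter, index=False)


def write_json_metadata(metadata: dict[str, Any], path: str | Path) -> None:
    """Dump run metadata as indented JSON (numpy types coerced)."""

    def _default(o):
        if isinstance(o, np.integer):
            return int(o)
        if isinstance(o, np.floating):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"cannot serialize {type(o)}")

    Path(path).write_text(json.dumps(metadata, indent=2, default=_default) + "\n")
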