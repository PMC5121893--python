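"""Reading, validation and normalisation of gene-by-sample expression tables.

Expression values are assumed to be log2-normalized and non-negative: the
mass-action neighbor probabilities downstream are ratios of expression
levels and are only meaningful for non-negative inputs.  Raw counts or TPM
can be brought onto that scale with the ``log2p1`` transform.

In-memory containers are plain pandas objects: a genes × samples
``DataFrame`` for a matrix and a gene-indexed ``Series`` (``.name`` holds
the sample id) for a single profile.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "load_expression",
    "write_expression",
    "get_profile",
    "aggregate_reference",
]


def _validate_matrix(df: pd.DataFrame, *, source: str = "<matrix>") -> None:
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{source}: duplicate gene symbols after collapsing: {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"{source}: duplicate sample ids: {dups}")
    values = df.to_numpy()
    if not np.isfinite(values).all():
        gene, sample = _first_offender(df, ~np.isfinite(df.to_numpy()))
        raise ValueError(f"{source}: non-finite value for gene {gene!r}, sample {sample!r}")
    if (values < 0).any():
        gene, sample = _first_offender(df, df.to_numpy() < 0)
        raise ValueError(
            f"{source}: negative expression value for gene {gene!r}, sample {sample!r}; "
            "expression must be non-negative (use transform='log2p1' for raw counts)"
        )


def _first_offender(df: pd.DataFrame, mask: np.ndarray) -> tuple[str, str]:
    i, j = np.argwhere(mask)[0]
    return str(df.index[i]), str(df.columns[j])


def load_expression(
    path,
    transform: str = "none",
    duplicate_policy: str = "max",
) -> pd.DataFrame:
    """Load a TSV expression table (first column gene symbols, header sample ids).

    Parameters
    ----------
    path
        Tab-separated file; UTF-8, ``.`` decimal separator.
    transform
        ``"none"`` keeps values as stored (they must already be non-negative,
        typically log2-normalized); ``"log2p1"`` replaces each value x with
        log2(x + 1), for raw counts / TPM.
    duplicate_policy
        How duplicate gene rows (e.g. several probes mapping to one symbol)
        are collapsed: ``"max"`` (default, common probe→symbol convention)
        or ``"mean"``.

    Returns
    -------
    pandas.DataFrame
        genes × samples, float values, validated non-negative and finite.
    """
    if transform not in ("none", "log2p1"):
        raise ValueError(f"unknown transform {transform!r}; expected 'none' or 'log2p1'")
    if duplicate_policy not in ("max", "mean"):
        raise ValueError(f"unknown duplicate_policy {duplicate_policy!r}")

    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.name is None and raw.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns found")
    df = pd.DataFrame(index=raw.index.astype(str))
    for col in raw.columns:
        numeric = pd.to_numeric(raw[col], errors="coerce")
        bad = numeric.isna() & raw[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            # +2: one for the header line, one for 1-based numbering
            raise ValueError(
                f"{path}: non-numeric cell {raw[col].iloc[row]!r} for gene "
                f"{raw.index[row]!r}, sample {col!r} (line {row + 2})"
            )
        if numeric.isna().any():
            row = int(np.flatnonzero(numeric.isna().to_numpy())[0])
            raise ValueError(
                f"{path}: empty cell for gene {raw.index[row]!r}, sample {col!r} "
                f"(line {row + 2})"
            )
        df[col] = numeric.astype(float)

    if df.index.has_duplicates:
        n_dup = int(df.index.duplicated().sum())
        logger.warning(
            "%s: %d duplicate gene row(s) collapsed by %s", path, n_dup, duplicate_policy
        )
        grouped = df.groupby(level=0, sort=False)
        df = grouped.max() if duplicate_policy == "max" else grouped.mean()

    if (df.to_numpy() < 0).any():
        gene, sample = _first_offender(df, df.to_numpy() < 0)
        raise ValueError(
            f"{path}: negative value for gene {gene!r}, sample {sample!r} "
            f"with transform={transform!r}"
        )
    if transform == "log2p1":
        df = np.log2(df + 1.0)

    _validate_matrix(df, source=str(path))
    return df


def write_expression(df: pd.DataFrame, path) -> None:
    """Write a genes × samples table back to TSV (round-trips full precision)."""
    out = df.copy()
    out.index.name = out.index.name or "gene"
    out.to_csv(path, sep="\t")


def get_profile(df: pd.DataFrame, sample_id: str) -> pd.Series:
    """Extract one sample column as an expression profile."""
    if sample_id not in df.columns:
        raise KeyError(f"sample {sample_id!r} not in matrix")
    return df[sample_id]


def aggregate_reference(
    df: pd.DataFrame,
    sample_ids: Sequence[str] | None = None,
    label: str = "reference",
    scale: str = "log",
) -> pd.Series:
    """Aggregate several (normal) samples into a single reference profile.

    The reference is the per-gene arithmetic mean of the log2-scale values
    (``scale="log"``, the default).  ``scale="linear"`` instead averages the
    back-transformed values 2**x − 1 and re-applies log2(·+1).

    Parameters
    ----------
    df
        genes × samples matrix of log2-normalized values.
    sample_ids
        Columns to aggregate; all columns if None.
    label
        ``.name`` of the returned Series.
    """
    if sample_ids is None:
        sample_ids = list(df.columns)
    if len(sample_ids) == 0:
        raise ValueError("need at least one sample to aggregate")
    missing = [s for s in sample_ids if s not in df.columns]
    if missing:
        raise KeyError(f"unknown sample id(s): {missing}")
    sub = df[list(sample_ids)]
    if scale == "log":
        ref = sub.mean(axis=1)
    elif scale == "linear":
        ref = np.log2((2.0 ** sub - 1.0).mean(axis=1) + 1.0)
    else:
        raise ValueError(f"unknown scale {scale!r}; expected 'log' or 'linear'")
    ref.name = label
    return ref
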