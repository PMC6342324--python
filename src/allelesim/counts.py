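"""Per-cell allelic count tables.

The unit of all model fitting is a table with one row per cell and integer
columns ``n_bl6`` and ``n_jf1`` (transcripts assigned to the C57BL/6J and
JF1/Ms allele, respectively), plus optional ``n_unassigned`` / ``n_dual``
columns for guide spots that matched no allele channel or both, and an
optional ``total`` column recording the pre-downsampling RNA count of the
cell.  Tables are plain :class:`pandas.DataFrame` objects so they compose
with the rest of the scientific Python stack; this module holds the schema
helpers and TSV round-trip.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "COUNT_COLUMNS",
    "make_counts",
    "validate_counts",
    "read_counts_tsv",
    "write_counts_tsv",
]

COUNT_COLUMNS = ("cell_id", "n_bl6", "n_jf1", "n_unassigned", "n_dual")


def make_counts(
    n_bl6,
    n_jf1,
    n_unassigned=None,
    n_dual=None,
    total=None,
    cell_id=None,
) -> pd.DataFrame:
    """Assemble a per-cell allelic count table.

    Parameters
    ----------
    n_bl6, n_jf1 : array-like of int
        Per-cell counts of uniquely assigned RNAs for each allele.
    n_unassigned, n_dual : array-like of int, optional
        RNAs with no / ambiguous allelic identity (default 0).
    total : array-like of int, optional
        Pre-downsampling total RNA count per cell; must be >= n_bl6 + n_jf1.
    cell_id : array-like, optional
        Cell identifiers (default 0..n-1).
    """
    n_bl6 = np.asarray(n_bl6, dtype=np.int64)
    n_jf1 = np.asarray(n_jf1, dtype=np.int64)
    n = len(n_bl6)
    df = pd.DataFrame(
        {
            "cell_id": np.arange(n) if cell_id is None else np.asarray(cell_id),
            "n_bl6": n_bl6,
            "n_jf1": n_jf1,
            "n_unassigned": np.zeros(n, dtype=np.int64)
            if n_unassigned is None
            else np.asarray(n_unassigned, dtype=np.int64),
            "n_dual": np.zeros(n, dtype=np.int64)
            if n_dual is None
            else np.asarray(n_dual, dtype=np.int64),
        }
    )
    if total is not None:
        df["total"] = np.asarray(total, dtype=np.int64)
    validate_counts(df)
    return df


def validate_counts(df: pd.DataFrame) -> pd.DataFrame:
    """Check schema and invariants; return the table unchanged."""
    for col in ("n_bl6", "n_jf1"):
        if col not in df.columns:
            raise ValueError(f"count table missing required column {col!r}")
        if (df[col] < 0).any():
            raise ValueError(f"negative counts in column {col!r}")
    if "total" in df.columns:
        if (df["total"] < df["n_bl6"] + df["n_jf1"]).any():
            raise ValueError("total must be >= n_bl6 + n_jf1 in every cell")
    return df


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    return validate_counts(pd.read_csv(path, sep="\t"))


def write_counts_tsv(df: pd.DataFrame, path: str | Path) -> None:
    validate_counts(df)
    df.to_csv(path, sep="\t", index=False)
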