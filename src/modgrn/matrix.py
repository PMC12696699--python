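"""Expression-matrix container conventions and TSV input/output.

The in-memory expression matrix is a pandas DataFrame with gene ids as the
row index and sample ids as columns; entries are finite reals (non-negative
on the raw FPKM-like scale, any sign after transformation). All pipeline
functions accept and return this shape.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class ExpressionError(ValueError):
    """Raised when an expression matrix violates its contract."""


def validate_expression(X: pd.DataFrame, require_nonnegative: bool = False) -> pd.DataFrame:
    """Check an expression DataFrame (genes x samples) against its invariants.

    Parameters
    ----------
    X : DataFrame
        Genes as rows, samples as columns.
    require_nonnegative : bool
        Enforce values >= 0 (the raw-scale precondition of the log transform).

    Returns
    -------
    DataFrame
        The validated input (float dtype).
    """
    if X.index.duplicated().any():
        dups = X.index[X.index.duplicated()].unique().tolist()
        raise ExpressionError(f"duplicate gene ids: {dups[:5]}")
    if X.columns.duplicated().any():
        dups = X.columns[X.columns.duplicated()].unique().tolist()
        raise ExpressionError(f"duplicate sample ids: {dups[:5]}")
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ExpressionError(f"matrix too small: {X.shape} (need >= 2 genes and 2 samples)")
    vals = X.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        gi, sj = np.argwhere(~np.isfinite(vals))[0]
        raise ExpressionError(
            f"non-finite value at gene {X.index[gi]!r}, sample {X.columns[sj]!r}"
        )
    if require_nonnegative and (vals < 0).any():
        gi, sj = np.argwhere(vals < 0)[0]
        raise ExpressionError(
            f"negative value at gene {X.index[gi]!r}, sample {X.columns[sj]!r}"
        )
    return X.astype(float)


def read_expression(path, sep: str = "\t") -> pd.DataFrame:
    """Read a genes-as-rows expression table (first column gene id, header row sample ids)."""
    X = pd.read_csv(path, sep=sep, index_col=0)
    X.index = X.index.astype(str)
    X.columns = X.columns.astype(str)
    return validate_expression(X)


def write_expression(X: pd.DataFrame, path, sep: str = "\t") -> None:
    X.to_csv(path, sep=sep, index_label="gene_id")


def read_trait(path, sep: str = "\t") -> pd.Series:
    """Read a two-column (sample_id, trait) table into a Series indexed by sample."""
    t = pd.read_csv(path, sep=sep, index_col=0)
    if t.shape[1] < 1:
        raise ExpressionError("trait file needs a sample_id column and a trait column")
    s = t.iloc[:, 0].astype(float)
    s.index = s.index.astype(str)
    return s
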