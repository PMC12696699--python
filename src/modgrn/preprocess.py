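"""Expression preprocessing: log transform, MAD gene filter, sample-outlier removal.

Three steps applied in order to a raw FPKM-like matrix:

1. ``log_transform`` — entrywise log(1 + I_ij) to compress the dynamic range.
2. ``mad_filter`` — per-gene median absolute deviation; by default the k
   most variable (highest-MAD) genes are retained, since near-constant genes
   carry no coexpression signal.
3. ``remove_outlier_samples`` — per-sample mean Euclidean distance to all
   other samples; samples whose statistic exceeds a threshold are dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .matrix import ExpressionError, validate_expression


@dataclass
class PreprocessReport:
    """Bookkeeping for a preprocessing step."""

    genes_in: int
    genes_out: int
    samples_in: int
    samples_out: int
    mad_per_gene: pd.Series | None = None
    sample_statistic: pd.Series | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.genes_out > self.genes_in:
            raise ValueError("genes_out > genes_in")
        if self.samples_out > self.samples_in:
            raise ValueError("samples_out > samples_in")

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "genes_in": self.genes_in,
            "genes_out": self.genes_out,
            "samples_in": self.samples_in,
            "samples_out": self.samples_out,
            **{f"param_{k}": v for k, v in self.params.items()},
        }
        return pd.DataFrame({"key": list(rows), "value": list(rows.values())})


def log_transform(X: pd.DataFrame, base: str = "e") -> pd.DataFrame:
    """Entrywise log(1 + I_ij); shape and ids unchanged.

    ``base`` is "e" (natural log, default) or "2"; the two differ only by a
    monotone scale factor.
    """
    X = validate_expression(X, require_nonnegative=True)
    out = np.log1p(X)
    if base == "2":
        out = out / np.log(2)
    elif base != "e":
        raise ValueError(f"unknown log base {base!r}")
    return out


def gene_mad(X: pd.DataFrame) -> pd.Series:
    """Per-gene median absolute deviation: median_j |I_ij - median_j(I_ij)|."""
    vals = X.to_numpy(dtype=float)
    med = np.median(vals, axis=1, keepdims=True)
    return pd.Series(np.median(np.abs(vals - med), axis=1), index=X.index, name="mad")


def mad_filter(
    X: pd.DataFrame,
    mode: str = "top_k",
    k_or_threshold: float = 15000,
    retain: str = "above",
) -> tuple[pd.DataFrame, PreprocessReport]:
    """Filter genes by median absolute deviation.

    mode="top_k": retain the k highest-MAD genes (ties broken by input
    order); this keeps the genes whose variation carries coexpression
    signal. mode="absolute": retain genes with MAD strictly above (default)
    or strictly below ``k_or_threshold`` per the ``retain`` flag.
    Retained genes keep their input order.
    """
    X = validate_expression(X)
    mad = gene_mad(X)
    m = len(mad)
    if mode == "top_k":
        k = int(k_or_threshold)
        if k <= 0:
            raise ValueError(f"k must be positive, got {k}")
        k = min(k, m)
        # stable sort on -mad: ties resolved in favour of earlier input rows
        order = np.argsort(-mad.to_numpy(), kind="stable")[:k]
        keep_mask = np.zeros(m, dtype=bool)
        keep_mask[order] = True
    elif mode == "absolute":
        thr = float(k_or_threshold)
        if thr < 0:
            raise ValueError(f"threshold must be >= 0, got {thr}")
        if retain == "above":
            keep_mask = mad.to_numpy() > thr
        elif retain == "below":
            keep_mask = mad.to_numpy() < thr
        else:
            raise ValueError(f"retain must be 'above' or 'below', got {retain!r}")
    else:
        raise ValueError(f"mode must be 'top_k' or 'absolute', got {mode!r}")

    Xf = X.loc[keep_mask]
    report = PreprocessReport(
        genes_in=m,
        genes_out=int(keep_mask.sum()),
        samples_in=X.shape[1],
        samples_out=X.shape[1],
        mad_per_gene=mad,
        params={"mode": mode, "k_or_threshold": k_or_threshold, "retain": retain},
    )
    return Xf, report


def sample_distance_matrix(X: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distances between sample columns."""
    D = squareform(pdist(X.to_numpy(dtype=float).T, metric="euclidean"))
    return pd.DataFrame(D, index=X.columns, columns=X.columns)


def remove_outlier_samples(
    X: pd.DataFrame,
    alpha: float | None = None,
    stat: str = "mean_distance",
    alpha_sd: float = 3.0,
) -> tuple[pd.DataFrame, PreprocessReport]:
    """Drop samples whose mean Euclidean distance to all others is extreme.

    The per-sample statistic is the mean distance to every other sample
    (``stat="mean_distance"``) or its z-score (``stat="zscore"``). A sample
    is dropped when its statistic exceeds ``alpha``; when ``alpha`` is None
    it defaults to mean + alpha_sd * sd of the statistic (mean_distance
    mode) or to ``alpha_sd`` itself (zscore mode).
    """
    X = validate_expression(X)
    if X.shape[1] < 3:
        raise ExpressionError("need at least 3 samples for outlier screening")
    D = sample_distance_matrix(X).to_numpy()
    n = D.shape[0]
    mean_dist = D.sum(axis=1) / (n - 1)
    if stat == "mean_distance":
        statistic = mean_dist
        if alpha is None:
            alpha = float(mean_dist.mean() + alpha_sd * mean_dist.std(ddof=1))
    elif stat == "zscore":
        sd = mean_dist.std(ddof=1)
        statistic = (mean_dist - mean_dist.mean()) / sd if sd > 0 else np.zeros(n)
        if alpha is None:
            alpha = float(alpha_sd)
    else:
        raise ValueError(f"stat must be 'mean_distance' or 'zscore', got {stat!r}")

    keep = statistic <= alpha
    if not keep.any():
        raise ExpressionError(
            f"alpha={alpha:g} removes every sample; refusing to return an empty matrix"
        )
    dropped = int((~keep).sum())
    if dropped:
        warnings.warn(f"removed {dropped} outlier sample(s)", stacklevel=2)
    Xf = X.loc[:, keep]
    report = PreprocessReport(
        genes_in=X.shape[0],
        genes_out=X.shape[0],
        samples_in=n,
        samples_out=int(keep.sum()),
        sample_statistic=pd.Series(statistic, index=X.columns, name=stat),
        params={"alpha": alpha, "stat": stat, "alpha_sd": alpha_sd},
    )
    return Xf, report
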