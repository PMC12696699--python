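"""Prognostic-index scoring of samples from key-gene expression.

PI_j = sum_i beta_i * I_ij, where beta_i is a Cox regression coefficient
supplied by the caller (fit with any standard survival library) and I_ij
the expression of key gene i in sample j. The classification threshold is
the PI of the per-gene-median pseudo-sample; samples strictly above it are
labelled "high" (diseased), the rest "low".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def _coef_series(genes, coefs) -> pd.Series:
    s = pd.Series(np.asarray(coefs, dtype=float), index=list(genes))
    if not np.isfinite(s.to_numpy()).all():
        raise ValueError("coefficients must be finite")
    return s


def _check_genes(X: pd.DataFrame, genes) -> list:
    genes = list(genes)
    missing = [g for g in genes if g not in X.index]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing[:5]}")
    return genes


def prognostic_index(X: pd.DataFrame, genes, coefs) -> pd.Series:
    """Per-sample linear risk score PI_j = sum_i beta_i * I_ij."""
    genes = _check_genes(X, genes)
    beta = _coef_series(genes, coefs)
    pi = beta.to_numpy() @ X.loc[genes].to_numpy(dtype=float)
    return pd.Series(pi, index=X.columns, name="PI")


def pi_threshold(X: pd.DataFrame, genes, coefs, rule: str = "median_profile") -> float:
    """Classification threshold for the prognostic index.

    rule="median_profile" (default): PI of the per-gene-median pseudo-sample,
    sum_i beta_i * median_j(I_ij). rule="median_pi": median of the per-sample
    PI values.
    """
    genes = _check_genes(X, genes)
    beta = _coef_series(genes, coefs)
    if rule == "median_profile":
        med = np.median(X.loc[genes].to_numpy(dtype=float), axis=1)
        return float(beta.to_numpy() @ med)
    if rule == "median_pi":
        return float(np.median(prognostic_index(X, genes, coefs)))
    raise ValueError(f"unknown rule {rule!r}")


def classify_samples(pi: pd.Series, threshold: float) -> pd.Series:
    """Label samples: PI strictly above the threshold -> "high", else "low"."""
    pi = pd.Series(pi)
    return pd.Series(
        np.where(pi.to_numpy(dtype=float) > threshold, "high", "low"),
        index=pi.index,
        name="class",
    )


@dataclass
class PrognosticModel:
    """Bundled coefficients, threshold, and per-sample scores/classes."""

    genes: list
    coefficients: np.ndarray
    threshold: float
    pi: pd.Series
    classes: pd.Series

    @classmethod
    def fit(cls, X: pd.DataFrame, genes, coefs, rule: str = "median_profile") -> "PrognosticModel":
        pi = prognostic_index(X, genes, coefs)
        thr = pi_threshold(X, genes, coefs, rule=rule)
        return cls(list(genes), np.asarray(coefs, float), thr, pi, classify_samples(pi, thr))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.pi.index, "PI": self.pi.to_numpy(), "class": self.classes.to_numpy()}
        )
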