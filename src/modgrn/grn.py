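"""GRN assembly from pair scores, reference coverage, and the two baselines.

The trained pair classifier scores every unordered key-gene pair; scores
above a cutoff (default 0.9) form the predicted undirected GRN. Coverage
counts how many predicted edges appear in reference edge lists. Two
baselines share the protocol: a random forest on the concatenated
expression vectors of the two genes, and a plug-in mutual-information
score on the binned joint distribution with a quantile cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .cnn import CNNPairClassifier, EvalReport, TrainConfig, evaluate
from .pairdata import EdgeList, LabeledPairSet, _canon, pair_histograms


@dataclass
class GRNEdgeList:
    """Scored, thresholded, undirected predicted network."""

    edges: pd.DataFrame  # gene_a, gene_b, score (sorted by score desc)
    threshold: float
    method: str = "cnn"

    def __len__(self) -> int:
        return len(self.edges)

    def as_set(self) -> set:
        return {_canon(a, b) for a, b in zip(self.edges["gene_a"], self.edges["gene_b"])}


@dataclass
class CoverageReport:
    """Predicted-edge counts confirmed per reference and in their union."""

    n_predicted: int
    confirmed: dict = field(default_factory=dict)  # ref name -> count
    union_confirmed: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [{"reference": k, "confirmed": v} for k, v in self.confirmed.items()]
        rows.append({"reference": "union", "confirmed": self.union_confirmed})
        df = pd.DataFrame(rows)
        df.insert(0, "n_predicted", self.n_predicted)
        return df


def score_pairs(
    model: CNNPairClassifier, X: pd.DataFrame, genes: list, bins: int = 32
) -> pd.DataFrame:
    """Score every unordered pair among ``genes``; returns (gene_a, gene_b, score)."""
    genes = list(genes)
    missing = [g for g in genes if g not in X.index]
    if missing:
        raise KeyError(f"genes not in expression matrix: {missing[:5]}")
    pairs = [_canon(a, b) for a, b in combinations(genes, 2)]
    hists = pair_histograms(X, pairs, bins=bins)
    scores = model.predict_proba(hists)
    return pd.DataFrame(
        {"gene_a": [p[0] for p in pairs], "gene_b": [p[1] for p in pairs], "score": scores}
    )


def threshold_grn(scored: pd.DataFrame, cutoff: float = 0.9, method: str = "cnn") -> GRNEdgeList:
    """Retain edges with score strictly above the cutoff, sorted by score descending."""
    kept = scored[scored["score"] > cutoff]
    kept = kept.sort_values(["score", "gene_a", "gene_b"], ascending=[False, True, True])
    return GRNEdgeList(kept.reset_index(drop=True), cutoff, method)


def top_regulators(
    model: CNNPairClassifier,
    X: pd.DataFrame,
    target_gene: str,
    candidates: list,
    k: int = 15,
    bins: int = 32,
) -> pd.DataFrame:
    """Rank candidate partners of a target gene by association score (top k)."""
    candidates = list(candidates)
    if target_gene in candidates:
        raise ValueError("target gene must not be among the candidates")
    if k > len(candidates):
        warnings.warn(f"k={k} exceeds {len(candidates)} candidates; returning all", stacklevel=2)
        k = len(candidates)
    # fixed (target, candidate) orientation: identical candidates score identically
    pairs = [(target_gene, c) for c in candidates]
    hists = pair_histograms(X, pairs, bins=bins)
    scores = model.predict_proba(hists)
    out = pd.DataFrame({"gene": candidates, "score": scores})
    out = out.sort_values(["score", "gene"], ascending=[False, True], kind="stable")
    return out.head(k).reset_index(drop=True)


def coverage(pred: GRNEdgeList, refs: dict[str, EdgeList]) -> CoverageReport:
    """Count predicted edges present (undirected match) in each reference and their union."""
    pred_set = pred.as_set()
    if not pred_set:
        warnings.warn("empty predicted GRN; coverage is zero", stacklevel=2)
    confirmed = {name: len(pred_set & ref.as_set()) for name, ref in refs.items()}
    union = set().union(*(ref.as_set() for ref in refs.values())) if refs else set()
    return CoverageReport(len(pred_set), confirmed, len(pred_set & union))


# ---------------------------------------------------------------- baselines


def _spliced_features(X: pd.DataFrame, pairs: list) -> np.ndarray:
    """Per pair, the two genes' expression vectors concatenated (gene_a first)."""
    vals = X
    return np.stack(
        [np.r_[vals.loc[a].to_numpy(float), vals.loc[b].to_numpy(float)] for a, b in pairs]
    )


def rf_baseline(
    X: pd.DataFrame,
    pairset: LabeledPairSet,
    seed: int = 0,
    n_trees: int = 500,
) -> tuple[np.ndarray, EvalReport]:
    """Random-forest baseline on spliced expression vectors, same CV protocol.

    Uses the fold assignment already present on ``pairset``; pooled held-out
    probabilities give the report. Deterministic given ``seed``.
    """
    if pairset.folds is None:
        raise ValueError("pairset has no fold assignment; call kfold_split first")
    feats = _spliced_features(X, pairset.pairs)
    scores = np.full(len(pairset), np.nan)
    rows = []
    for f in np.unique(pairset.folds):
        test = pairset.folds == f
        clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed + int(f))
        clf.fit(feats[~test], pairset.labels[~test])
        scores[test] = clf.predict_proba(feats[test])[:, 1]
        rep = evaluate(scores[test], pairset.labels[test])
        rows.append({"fold": int(f), "n": int(test.sum()), "accuracy": rep.accuracy,
                     "tpr": rep.tpr, "fpr": rep.fpr, "auc": rep.auc})
    pooled = evaluate(scores, pairset.labels)
    pooled.per_fold = pd.DataFrame(rows)
    pooled.fold_ids = pairset.folds.copy()
    return scores, pooled


def mutual_information(x: np.ndarray, y: np.ndarray, bins: int = 8) -> float:
    """Plug-in mutual information (nats) of the equal-width binned joint distribution.

    Returns NaN when either vector is constant (the joint distribution
    degenerates and dependence is undefined).
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    joint, _, _ = np.histogram2d(x, y, bins=bins)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float((p[nz] * np.log(p[nz] / (px @ py)[nz])).sum())


def mi_pair_scores(X: pd.DataFrame, pairs: list, bins: int = 8) -> np.ndarray:
    """Mutual information per gene pair (NaN for pairs touching a constant gene)."""
    return np.array(
        [mutual_information(X.loc[a].to_numpy(float), X.loc[b].to_numpy(float), bins)
         for a, b in pairs]
    )


def mi_grn(
    X: pd.DataFrame, genes: list, bins: int = 8, quantile_cut: float = 0.95
) -> GRNEdgeList:
    """Mutual-information network: retain pairs scoring above the score quantile."""
    if not 0 < quantile_cut < 1:
        raise ValueError("quantile_cut must be in (0, 1)")
    pairs = [_canon(a, b) for a, b in combinations(list(genes), 2)]
    scores = mi_pair_scores(X, pairs, bins=bins)
    if np.isnan(scores).any():
        warnings.warn(
            f"{int(np.isnan(scores).sum())} pair(s) with constant gene: MI undefined",
            stacklevel=2,
        )
    finite = scores[~np.isnan(scores)]
    cut = float(np.quantile(finite, quantile_cut)) if finite.size else float("nan")
    df = pd.DataFrame(
        {"gene_a": [p[0] for p in pairs], "gene_b": [p[1] for p in pairs], "score": scores}
    )
    kept = df[df["score"] > cut].sort_values(
        ["score", "gene_a", "gene_b"], ascending=[False, True, True]
    )
    return GRNEdgeList(kept.reset_index(drop=True), cut, "mi")
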