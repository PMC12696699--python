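"""Labeled gene-pair datasets and joint-expression histograms.

Positives are edges of a prior interaction network (e.g. a STRING export
restricted to one module); negatives are uniformly sampled non-edges over
the same gene universe. Each unordered pair is summarized as a 32x32 joint
histogram: each gene's expression range [min, max] is split into 32 equal
subintervals and every sample increments the cell indexed by its two bin
coordinates. Pairs are stored with the lexicographically smaller gene id
first so features are orientation-deterministic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

logger = logging.getLogger(__name__)

_HEADER_TOKENS = {
    "gene_a", "gene_b", "gene1", "gene2", "protein1", "protein2",
    "node1", "node2", "source", "target", "score", "combined_score",
}


def _canon(a, b) -> tuple:
    return (a, b) if str(a) <= str(b) else (b, a)


@dataclass
class EdgeList:
    """Undirected, deduplicated gene-pair set with optional per-edge scores."""

    edges: list = field(default_factory=list)  # list of canonical (a, b) tuples
    scores: dict = field(default_factory=dict)
    source: str = ""

    def __post_init__(self):
        seen = set()
        canon = []
        for a, b in self.edges:
            e = _canon(a, b)
            if e[0] == e[1] or e in seen:
                continue
            seen.add(e)
            canon.append(e)
        self.edges = canon
        self._set = seen

    def __len__(self) -> int:
        return len(self.edges)

    def __contains__(self, pair) -> bool:
        return _canon(*pair) in self._set

    def as_set(self) -> set:
        return set(self._set)

    def restrict(self, universe) -> "EdgeList":
        u = set(universe)
        kept = [e for e in self.edges if e[0] in u and e[1] in u]
        return EdgeList(kept, {e: self.scores[e] for e in kept if e in self.scores}, self.source)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene_a": a, "gene_b": b, "score": self.scores.get((a, b), np.nan)}
            for a, b in self.edges
        ]
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"])


def load_edge_list(path, score_cut: float | None = None, universe=None, sep: str = "\t") -> EdgeList:
    """Read a two/three-column (gene_a, gene_b[, score]) edge list.

    Undirected duplicates and self-loops are dropped; edges with either
    endpoint outside ``universe`` (if given) are dropped; edges with score
    below ``score_cut`` (if given) are dropped. A header row is detected by
    its column tokens.
    """
    try:
        raw = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error passthrough
        raise IOError(f"cannot read edge list {path}: {exc}") from exc
    if raw.shape[1] < 2:
        raise IOError(f"edge list {path} needs at least 2 columns")
    first = [str(v).strip().lower() for v in raw.iloc[0]]
    if any(tok in _HEADER_TOKENS for tok in first):
        raw = raw.iloc[1:]
    if raw.empty:
        raise IOError(f"edge list {path} has no data rows")

    n_in = len(raw)
    edges, scores = [], {}
    universe = set(universe) if universe is not None else None
    for row in raw.itertuples(index=False):
        a, b = str(row[0]).strip(), str(row[1]).strip()
        score = None
        if len(row) > 2 and row[2] is not None and str(row[2]).strip() not in ("", "nan"):
            try:
                score = float(row[2])
            except ValueError:
                score = None
        if a == b:
            continue
        if universe is not None and (a not in universe or b not in universe):
            continue
        if score_cut is not None and score is not None and score < score_cut:
            continue
        e = _canon(a, b)
        edges.append(e)
        if score is not None:
            scores[e] = score
    el = EdgeList(edges, scores, source=str(path))
    if len(el) == 0:
        raise IOError(f"edge list {path}: no valid edges after filtering")
    logger.info("edge list %s: %d rows -> %d unique edges", path, n_in, len(el))
    return el


def write_edge_list(el: EdgeList, path, sep: str = "\t") -> None:
    el.to_frame().to_csv(path, sep=sep, index=False)


def sample_negatives(universe, prior: EdgeList, n_neg: int, seed: int) -> list:
    """Sample ``n_neg`` distinct unordered non-self pairs absent from ``prior``.

    Mirrors the randomized strategy of drawing two endpoints at random and
    skipping draws already present in the prior network; when the feasible
    space is small relative to the request the complement is enumerated and
    sampled exactly. Reproducible given ``seed``.
    """
    genes = list(universe)
    n = len(genes)
    prior_in = len(prior.restrict(genes))
    feasible = n * (n - 1) // 2 - prior_in
    if n_neg > feasible:
        raise ValueError(
            f"requested {n_neg} negatives but only {feasible} non-edges exist"
        )
    rng = np.random.default_rng(seed)
    if feasible <= max(4 * n_neg, 10_000):
        allpairs = [e for e in (_canon(a, b) for a, b in combinations(genes, 2)) if e not in prior]
        idx = rng.choice(len(allpairs), size=n_neg, replace=False)
        return [allpairs[i] for i in sorted(idx)]
    out, seen = [], set()
    while len(out) < n_neg:
        a, b = rng.integers(0, n, size=2)
        if a == b:
            continue
        e = _canon(genes[a], genes[b])
        if e in prior or e in seen:
            continue
        seen.add(e)
        out.append(e)
    return out


@dataclass
class PairHistogram:
    """32x32 joint-expression count grid for one gene pair."""

    counts: np.ndarray  # (bins, bins) int, rows = gene_a bins
    gene_a: str = ""
    gene_b: str = ""
    edges_a: np.ndarray | None = None
    edges_b: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return int(self.counts.sum())


def _bin_vector(x: np.ndarray, bins: int) -> np.ndarray:
    """Equal-width bin index per sample; the maximum lands in the last bin."""
    lo, hi = x.min(), x.max()
    if hi == lo:
        warnings.warn("degenerate expression range; all samples assigned bin 0", stacklevel=3)
        return np.zeros(x.shape, dtype=np.int64)
    idx = np.floor(bins * (x - lo) / (hi - lo)).astype(np.int64)
    return np.clip(idx, 0, bins - 1)


def pair_histogram(x_a, x_b, bins: int = 32, gene_a: str = "", gene_b: str = "") -> PairHistogram:
    """Joint histogram of two per-sample expression vectors.

    Per gene, bin index = floor(bins * (x - min)/(max - min)) clipped so the
    maximum falls in the last bin; ``counts[i, j]`` is the number of samples
    with gene_a in bin i and gene_b in bin j. A constant vector degenerates
    to bin 0 for every sample (with a warning).
    """
    x_a = np.asarray(x_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    if x_a.shape != x_b.shape or x_a.ndim != 1 or x_a.size < 1:
        raise ValueError(f"vectors must be equal-length 1-D, got {x_a.shape} vs {x_b.shape}")
    ia = _bin_vector(x_a, bins)
    ib = _bin_vector(x_b, bins)
    counts = np.bincount(ia * bins + ib, minlength=bins * bins).reshape(bins, bins)
    return PairHistogram(
        counts,
        gene_a,
        gene_b,
        edges_a=np.linspace(x_a.min(), x_a.max(), bins + 1),
        edges_b=np.linspace(x_b.min(), x_b.max(), bins + 1),
    )


def pair_histograms(X: pd.DataFrame, pairs: list, bins: int = 32) -> np.ndarray:
    """Stack of joint histograms, shape (n_pairs, bins, bins).

    Bin indices are computed once per gene, so building thousands of pair
    histograms stays cheap.
    """
    genes = sorted({g for p in pairs for g in p})
    vals = X.loc[genes].to_numpy(dtype=float)
    bin_idx = np.vstack([_bin_vector(row, bins) for row in vals])
    pos = {g: i for i, g in enumerate(genes)}
    out = np.empty((len(pairs), bins, bins), dtype=np.int64)
    for k, (a, b) in enumerate(pairs):
        flat = bin_idx[pos[a]] * bins + bin_idx[pos[b]]
        out[k] = np.bincount(flat, minlength=bins * bins).reshape(bins, bins)
    return out


@dataclass
class LabeledPairSet:
    """Gene pairs with binary labels and optional cross-validation folds."""

    pairs: list  # canonical (a, b) tuples
    labels: np.ndarray  # int {0, 1}
    folds: np.ndarray | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.pairs) != len(self.labels):
            raise ValueError("pairs and labels length mismatch")
        if set(np.unique(self.labels)) - {0, 1}:
            raise ValueError("labels must be 0/1")
        if len({_canon(*p) for p in self.pairs}) != len(self.pairs):
            raise ValueError("duplicate pairs in labeled set")

    def __len__(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.pairs, columns=["gene_a", "gene_b"])
        df["label"] = self.labels
        if self.folds is not None:
            df["fold"] = self.folds
        return df


def build_labeled_dataset(
    X: pd.DataFrame,
    module_genes,
    prior: EdgeList,
    neg_ratio: float = 1.0,
    seed: int = 0,
    bins: int = 32,
) -> tuple[LabeledPairSet, np.ndarray]:
    """Positives from the prior restricted to module genes, sampled negatives, histograms.

    Negatives number round(neg_ratio * n_positives); the default 1:1 balance
    keeps the classifier's confidence distribution symmetric between the two
    classes. Returns the labeled set and an (n_pairs, bins, bins) histogram
    stack; deterministic given ``seed``.
    """
    module_genes = list(module_genes)
    pos = prior.restrict(module_genes).edges
    if not pos:
        raise ValueError("no prior edges among the given module genes")
    if neg_ratio < 0:
        raise ValueError("neg_ratio must be >= 0")
    n_neg = int(round(neg_ratio * len(pos)))
    neg = sample_negatives(module_genes, prior, n_neg, seed) if n_neg else []
    pairs = pos + neg
    labels = np.r_[np.ones(len(pos), dtype=int), np.zeros(len(neg), dtype=int)]
    pairset = LabeledPairSet(pairs, labels)
    hists = pair_histograms(X, pairs, bins=bins)
    return pairset, hists


def kfold_split(P: LabeledPairSet, K: int, seed: int, stratified: bool = True) -> LabeledPairSet:
    """Assign each pair to one of K cross-validation folds.

    Fold sizes differ by at most 1; stratified mode additionally preserves
    the label ratio per fold within one item. Returns a new LabeledPairSet
    with the ``folds`` field populated; reproducible given ``seed``.
    """
    if K < 2 or K > len(P):
        raise ValueError(f"K must be in [2, {len(P)}], got {K}")
    splitter = (
        StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
        if stratified
        else KFold(n_splits=K, shuffle=True, random_state=seed)
    )
    folds = np.empty(len(P), dtype=int)
    dummy = np.zeros(len(P))
    for f, (_, test_idx) in enumerate(splitter.split(dummy, P.labels)):
        folds[test_idx] = f
    return LabeledPairSet(P.pairs, P.labels, folds)
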