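"""Weighted coexpression core.

Builds the signed soft-threshold network from a gene x sample matrix and
extracts coexpression modules and key genes:

* Pearson correlation ``cor`` between gene rows;
* signed adjacency ``a_ij = ((1 + cor_ij) / 2) ** beta``, which maps
  correlation [-1, 1] onto [0, 1] and suppresses weak links for beta > 1;
* soft-threshold selection by scale-free topology fit: for each candidate
  beta, the connectivity distribution K_i = sum_u a_iu is binned and
  log10(frequency) is regressed on log10(mean K); the signed fit index is
  -sign(slope) * R^2 and the chosen beta is the smallest candidate whose
  index reaches the cut;
* topological overlap TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) /
  (min(K_i, K_j) + 1 - a_ij), a similarity that credits shared neighbours;
* average-linkage hierarchical clustering on 1 - TOM with a static tree
  cut, small clusters relabelled grey (label 0), and modules merged when
  their eigengenes are nearly collinear;
* module eigengenes (first principal component of the standardized member
  submatrix), module-trait correlation, and gene screening by gene
  significance (GS) and module membership (MM).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy import stats

from .matrix import validate_expression

GREY = 0  # reserved label for unassigned genes


class CorrelationError(ValueError):
    pass


def pearson_correlation(X: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between all gene rows; symmetric with unit diagonal.

    Raises if any gene row has zero variance (filter those genes first).
    """
    X = validate_expression(X)
    vals = X.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    if (sd == 0).any():
        bad = X.index[sd == 0].tolist()
        raise CorrelationError(f"zero-variance genes: {bad[:10]}")
    C = np.corrcoef(vals)
    C = np.clip(C, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return pd.DataFrame(C, index=X.index, columns=X.index)


def signed_adjacency(C: pd.DataFrame, beta: int) -> pd.DataFrame:
    """Signed soft-threshold adjacency a_ij = ((1 + cor_ij)/2)^beta; diagonal 1."""
    if int(beta) != beta or beta < 1:
        raise ValueError(f"beta must be an integer >= 1, got {beta}")
    A = ((1.0 + C.to_numpy(dtype=float)) / 2.0) ** int(beta)
    np.fill_diagonal(A, 1.0)
    return pd.DataFrame(A, index=C.index, columns=C.columns)


def connectivity(A: pd.DataFrame) -> pd.Series:
    """Network connectivity K_i = sum of adjacency to all *other* genes."""
    vals = A.to_numpy(dtype=float)
    K = vals.sum(axis=1) - np.diag(vals)
    return pd.Series(K, index=A.index, name="K")


def scale_free_fit(K: np.ndarray, n_bins: int = 10) -> float:
    """Signed scale-free topology fit index of a connectivity distribution.

    Bins K into ``n_bins`` equal-width bins, regresses log10(bin frequency)
    on log10(bin mean K), and returns -sign(slope) * R^2 so that the
    decreasing tail expected of a scale-free degree distribution scores
    positively. Returns NaN when fewer than 3 usable bins exist or the
    regression is degenerate.
    """
    K = np.asarray(K, dtype=float)
    K = K[K > 0]
    if K.size < 3 or np.ptp(K) == 0:
        return float("nan")
    edges = np.linspace(K.min(), K.max(), n_bins + 1)
    idx = np.clip(np.digitize(K, edges[1:-1]), 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    nonempty = counts > 0
    if nonempty.sum() < 3:
        return float("nan")
    mean_k = np.array([K[idx == b].mean() for b in np.nonzero(nonempty)[0]])
    freq = counts[nonempty] / K.size
    if np.ptp(np.log10(mean_k)) == 0 or np.ptp(np.log10(freq)) == 0:
        return float("nan")
    res = stats.linregress(np.log10(mean_k), np.log10(freq))
    return float(-np.sign(res.slope) * res.rvalue**2)


@dataclass
class SoftThresholdScan:
    """Result of scanning candidate soft-threshold powers."""

    betas: list[int]
    fit_index: list[float]
    mean_connectivity: list[float]
    chosen_beta: int
    fit_cut: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta": self.betas,
                "fit_index": self.fit_index,
                "mean_connectivity": self.mean_connectivity,
            }
        )


def pick_soft_threshold(
    X: pd.DataFrame,
    betas: list[int] | None = None,
    fit_cut: float = 0.85,
    n_bins: int = 10,
    corr: pd.DataFrame | None = None,
) -> SoftThresholdScan:
    """Scan soft-threshold powers and choose the smallest with adequate fit.

    For each beta the signed adjacency is built, connectivity computed, and
    the scale-free fit index evaluated. ``chosen_beta`` is the smallest
    candidate whose fit index reaches ``fit_cut``; if none does, the beta
    with the maximal fit is chosen with a warning. ``corr`` may be supplied
    to reuse a precomputed correlation matrix.
    """
    if betas is None:
        betas = list(range(1, 21))
    betas = [int(b) for b in betas]
    if not betas or sorted(betas) != betas:
        raise ValueError("betas must be a non-empty ascending list")
    C = pearson_correlation(X) if corr is None else corr
    fits, mean_k = [], []
    for b in betas:
        A = signed_adjacency(C, b)
        K = connectivity(A).to_numpy()
        fits.append(scale_free_fit(K, n_bins=n_bins))
        mean_k.append(float(K.mean()))
    chosen = None
    for b, f in zip(betas, fits):
        if np.isfinite(f) and f >= fit_cut:
            chosen = b
            break
    if chosen is None:
        finite = [(f, b) for b, f in zip(betas, fits) if np.isfinite(f)]
        if not finite:
            raise CorrelationError("scale-free fit undefined for every candidate beta")
        chosen = max(finite)[1]
        warnings.warn(
            f"no beta reached fit cut {fit_cut}; using beta={chosen} with max fit",
            stacklevel=2,
        )
    return SoftThresholdScan(betas, fits, mean_k, chosen, fit_cut)


def tom(A: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix from a symmetric adjacency in [0, 1].

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(K_i, K_j) + 1 - a_ij),
    with the adjacency diagonal excluded from all sums and TOM diagonal 1.
    """
    vals = A.to_numpy(dtype=float)
    if not np.allclose(vals, vals.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if vals.min() < -1e-12 or vals.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    A0 = vals.copy()
    np.fill_diagonal(A0, 0.0)
    K = A0.sum(axis=1)
    numer = A0 @ A0 + A0  # (A0@A0)_ij already omits u=i and u=j (diag of A0 is 0)
    denom = np.minimum.outer(K, K) + 1.0 - A0
    T = numer / denom
    np.fill_diagonal(T, 1.0)
    return pd.DataFrame(T, index=A.index, columns=A.columns)


def module_eigengene(X: pd.DataFrame, members: list) -> pd.Series:
    """First principal component of a module's standardized expression block.

    Member rows are z-scored over samples; the first right singular vector
    (unit norm over samples) is the eigengene, sign-oriented so that its
    correlation with the mean member profile is non-negative.
    """
    members = list(members)
    if len(members) < 2:
        raise ValueError("need at least 2 member genes")
    sub = X.loc[members].to_numpy(dtype=float)
    sd = sub.std(axis=1, ddof=1)
    if (sd == 0).all():
        raise CorrelationError("all member genes are constant")
    if (sd == 0).any():
        warnings.warn(f"excluding {int((sd == 0).sum())} constant member gene(s)", stacklevel=2)
        sub = sub[sd > 0]
        sd = sd[sd > 0]
    Z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
    _, _, Vt = np.linalg.svd(Z, full_matrices=False)
    eig = Vt[0]
    mean_profile = Z.mean(axis=0)
    if np.dot(eig, mean_profile) < 0:
        eig = -eig
    return pd.Series(eig, index=X.columns, name="eigengene")


@dataclass
class ModuleAssignment:
    """Per-gene module labels plus module eigengenes.

    Label 0 is the reserved grey id for unassigned genes; modules are
    numbered 1..M in descending size order.
    """

    labels: pd.Series
    eigengenes: pd.DataFrame  # modules x samples
    min_module_size: int
    merge_heights: np.ndarray | None = None

    @property
    def modules(self) -> list[int]:
        return [m for m in sorted(self.labels.unique()) if m != GREY]

    def members(self, module: int) -> list:
        return self.labels.index[self.labels == module].tolist()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene_id": self.labels.index, "module": self.labels.to_numpy()})


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Map cluster labels to 1..M by descending size (ties by old label), 0 stays 0."""
    out = np.zeros_like(labels)
    sizes = pd.Series(labels[labels != GREY]).value_counts()
    order = sorted(sizes.index, key=lambda m: (-sizes[m], m))
    for new, old in enumerate(order, start=1):
        out[labels == old] = new
    return out


def _best_static_cut(Z: np.ndarray, min_size: int) -> float:
    """Cut height maximizing the number of clusters with >= min_size members.

    Candidates are midpoints between successive distinct merge heights; on
    ties the highest cut wins (coarser, more stable clusters — loosely
    attached genes are handled downstream by eigengene-membership pruning).
    """
    heights = np.unique(Z[:, 2])
    if heights.size == 1:
        return float(heights[0])
    cand = (heights[:-1] + heights[1:]) / 2.0
    best_cut, best_count = float(cand[-1]), -1
    for cut in cand:
        labels = fcluster(Z, t=cut, criterion="distance")
        count = int((np.bincount(labels) >= min_size).sum())
        if count >= best_count:
            best_cut, best_count = float(cut), count
    return best_cut


def detect_modules(
    T: pd.DataFrame,
    X: pd.DataFrame,
    min_size: int = 30,
    cut_height: float | None = None,
    merge_cut: float = 0.9,
    kme_prune: float = 0.3,
) -> ModuleAssignment:
    """Detect coexpression modules by hierarchical clustering of 1 - TOM.

    Average linkage on the TOM dissimilarity; the tree is cut at
    ``cut_height``; when None, candidate cuts between successive merge
    heights are scanned and the cut revealing the most clusters of at least
    ``min_size`` members is chosen (the highest such cut on ties), a static
    analogue of adaptive tree cutting that is robust to the overall height
    scale of the dendrogram; members whose
    correlation with their cluster eigengene falls below ``kme_prune`` are
    relabelled grey (loose static cuts tend to absorb unconnected genes into
    otherwise clean clusters); clusters smaller than ``min_size`` are
    relabelled grey; modules whose eigengenes correlate above ``merge_cut``
    are merged; final labels are 1..M by descending module size. ``X``
    provides the expression used for eigengenes (same gene set as ``T``).
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    m = T.shape[0]
    if min_size > m:
        raise ValueError(f"min_size {min_size} exceeds gene count {m}")
    D = 1.0 - T.to_numpy(dtype=float)
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    if cut_height is None:
        cut_height = _best_static_cut(Z, min_size)
    labels = fcluster(Z, t=cut_height, criterion="distance")
    genes = T.index

    # eigengene-membership pruning of loosely attached genes
    if kme_prune > 0:
        Xv = X.loc[genes].to_numpy(dtype=float)
        for m_ in np.unique(labels):
            idx = np.nonzero(labels == m_)[0]
            if len(idx) < 2:
                continue
            eig = module_eigengene(X, genes[idx].tolist()).to_numpy()
            kme = _abs_corr_rows(Xv[idx], eig)
            labels[idx[kme < kme_prune]] = GREY

    # grey out undersized clusters
    sizes = pd.Series(labels).value_counts()
    small = sizes.index[sizes < min_size]
    labels = np.where(np.isin(labels, small), GREY, labels)

    # iterative eigengene merge: fuse the most correlated pair above merge_cut
    while True:
        mods = [m_ for m_ in np.unique(labels) if m_ != GREY]
        if len(mods) < 2:
            break
        eigs = {
            m_: module_eigengene(X, genes[labels == m_].tolist()).to_numpy() for m_ in mods
        }
        best, best_cor = None, merge_cut
        for i, a in enumerate(mods):
            for b in mods[i + 1 :]:
                c = float(np.corrcoef(eigs[a], eigs[b])[0, 1])
                if c > best_cor:
                    best, best_cor = (a, b), c
        if best is None:
            break
        labels = np.where(labels == best[1], best[0], labels)

    labels = _relabel_by_size(labels)
    lab = pd.Series(labels, index=genes, name="module")
    eig_rows = {
        m_: module_eigengene(X, lab.index[lab == m_].tolist())
        for m_ in sorted(set(labels))
        if m_ != GREY
    }
    eigengenes = pd.DataFrame(eig_rows).T
    eigengenes.index.name = "module"
    return ModuleAssignment(lab, eigengenes, min_size, merge_heights=Z[:, 2].copy())


def module_trait_correlation(M: ModuleAssignment, trait: pd.Series) -> pd.DataFrame:
    """Pearson correlation of each module eigengene with a sample trait.

    Returns a table (module, cor, p) sorted by |cor| descending; p is the
    two-sided t-approximation.
    """
    if M.eigengenes.empty:
        raise ValueError("assignment has no non-grey modules")
    t = trait.reindex(M.eigengenes.columns).to_numpy(dtype=float)
    if not np.isfinite(t).all():
        raise ValueError("trait missing or non-finite for some samples")
    if t.std() == 0:
        raise ValueError("trait has zero variance")
    rows = []
    for mod, eig in M.eigengenes.iterrows():
        r, p = stats.pearsonr(eig.to_numpy(), t)
        rows.append({"module": mod, "cor": r, "p": p})
    out = pd.DataFrame(rows)
    return out.reindex(out["cor"].abs().sort_values(ascending=False).index).reset_index(
        drop=True
    )


@dataclass
class GeneScreen:
    """GS/MM table and the ranked key-gene list for one module."""

    table: pd.DataFrame  # gene_id, module, GS, MM
    gs_threshold: float
    mm_threshold: float
    key_genes: list = field(default_factory=list)


def _abs_corr_rows(vals: np.ndarray, target: np.ndarray) -> np.ndarray:
    """|Pearson correlation| of each row of ``vals`` with ``target``."""
    vc = vals - vals.mean(axis=1, keepdims=True)
    tc = target - target.mean()
    denom = np.sqrt((vc**2).sum(axis=1) * (tc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (vc @ tc) / denom
    return np.abs(np.clip(r, -1.0, 1.0))


def select_key_genes(
    table: pd.DataFrame, gs_threshold: float, mm_threshold: float, top_n: int
) -> list:
    """Pure selection step: filter a (gene_id, GS, MM) table and rank.

    Candidates satisfy MM > mm_threshold and GS > gs_threshold; the top
    ``top_n`` by GS descending are returned (ties by MM descending, then
    gene id ascending).
    """
    cand = table[(table["MM"] > mm_threshold) & (table["GS"] > gs_threshold)]
    cand = cand.sort_values(
        by=["GS", "MM", "gene_id"], ascending=[False, False, True], kind="stable"
    )
    return cand["gene_id"].head(top_n).tolist()


def screen_key_genes(
    X: pd.DataFrame,
    M: ModuleAssignment,
    trait: pd.Series,
    module: int | None = None,
    gs_threshold: float = 0.2,
    mm_threshold: float = 0.8,
    top_n: int = 10,
) -> GeneScreen:
    """Select key genes of a module by gene significance and module membership.

    GS_i = |cor(X_i, trait)|; MM_i = |cor(X_i, module eigengene)|. Candidates
    are module members with MM > mm_threshold and GS > gs_threshold; key
    genes are the top ``top_n`` candidates by GS descending (ties by MM
    descending, then gene id). ``module`` defaults to the module most
    correlated with the trait.
    """
    if module is None:
        module = int(module_trait_correlation(M, trait)["module"].iloc[0])
    members = M.members(module)
    if not members:
        raise ValueError(f"module {module} has no members")
    sub = X.loc[members, M.eigengenes.columns].to_numpy(dtype=float)
    t = trait.reindex(M.eigengenes.columns).to_numpy(dtype=float)
    eig = M.eigengenes.loc[module].to_numpy(dtype=float)
    gs = _abs_corr_rows(sub, t)
    mm = _abs_corr_rows(sub, eig)
    table = pd.DataFrame({"gene_id": members, "module": module, "GS": gs, "MM": mm})
    key = select_key_genes(table, gs_threshold, mm_threshold, top_n)
    if not key:
        warnings.warn("no genes pass the GS/MM thresholds", stacklevel=2)
    return GeneScreen(table.reset_index(drop=True), gs_threshold, mm_threshold, key)
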