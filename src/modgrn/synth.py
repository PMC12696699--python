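"""Synthetic modular expression data with planted structure.

A Gaussian latent-factor model generates exactly the statistical structure
the coexpression pipeline assumes: each module m has a per-sample latent
factor f_m, and gene i in module m has latent profile
``z_i = lambda_i * f_m + noise_scale * sqrt(1 - lambda_i^2) * eps_i`` with
loading lambda_i drawn from a configurable range. Background genes are
pure noise. Planted regulatory edges connect above-median-loading genes
within a module and add a private shared component ``delta * g_e`` to both
endpoints, so edge pairs carry joint dependence beyond the module baseline
— the learnable signal for the pair classifier. The trait is the factor of
one designated module plus noise. Latent profiles are mapped to a
non-negative FPKM-like scale by ``exp(mean_log + sd_log * z)``, so the
preprocessing log transform is exercised end to end.

Everything is a deterministic function of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .pairdata import EdgeList, _canon


@dataclass
class SynthConfig:
    """Generator settings; defaults give 5 modules x 60 genes + 100 background
    over 200 samples with 80 planted edges per module (~400 positives)."""

    seed: int
    n_modules: int = 5
    genes_per_module: int = 60
    n_background_genes: int = 100
    n_samples: int = 200
    loading_range: tuple = (0.6, 0.95)
    edges_per_module: int = 80
    edge_boost: float = 0.6
    edge_form: str = "linear"  # or "quadratic" for a nonlinear dependence
    trait_module: int = 1
    trait_noise: float = 0.5
    noise_scale: float = 0.6
    mean_log: float = 2.0
    sd_log: float = 0.8

    def __post_init__(self):
        if min(self.n_modules, self.genes_per_module, self.n_samples) < 1:
            raise ValueError("counts must be >= 1")
        lo, hi = self.loading_range
        if not (0 < lo <= hi < 1):
            raise ValueError("loadings must lie in (0, 1)")
        if not 1 <= self.trait_module <= self.n_modules:
            raise ValueError("trait_module must name an existing module")
        if self.edge_form not in ("linear", "quadratic"):
            raise ValueError("edge_form must be 'linear' or 'quadratic'")


@dataclass
class SynthTruth:
    """Planted ground truth: module labels, edge set, trait, loadings."""

    module_labels: pd.Series  # gene -> module id (0 = background)
    edges: EdgeList
    trait: pd.Series
    loadings: pd.Series


@dataclass
class SynthData:
    """Generated instance: expression (FPKM-like), trait, prior network, truth."""

    expression: pd.DataFrame
    trait: pd.Series
    prior: EdgeList
    truth: SynthTruth
    config: SynthConfig = field(repr=False, default=None)

    def to_files(self, outdir) -> dict:
        """Write expr.tsv, trait.tsv, prior.tsv and truth.json; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "expr": outdir / "expr.tsv",
            "trait": outdir / "trait.tsv",
            "prior": outdir / "prior.tsv",
            "truth": outdir / "truth.json",
        }
        self.expression.to_csv(paths["expr"], sep="\t", index_label="gene_id")
        self.trait.rename("trait").to_frame().to_csv(paths["trait"], sep="\t", index_label="sample_id")
        self.prior.to_frame().to_csv(paths["prior"], sep="\t", index=False)
        truth = {
            "module_labels": self.truth.module_labels.to_dict(),
            "edges": [list(e) for e in self.truth.edges.edges],
            "loadings": self.truth.loadings.to_dict(),
            "config": asdict(self.config) if self.config else None,
        }
        paths["truth"].write_text(json.dumps(truth, indent=1))
        return paths


def generate(cfg: SynthConfig) -> SynthData:
    """Draw one synthetic instance; bit-identical for a fixed (config, seed)."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    m_mod = cfg.n_modules * cfg.genes_per_module
    m = m_mod + cfg.n_background_genes

    genes = [f"G{i:04d}" for i in range(1, m + 1)]
    samples = [f"S{j:03d}" for j in range(1, n + 1)]
    labels = np.r_[
        np.repeat(np.arange(1, cfg.n_modules + 1), cfg.genes_per_module),
        np.zeros(cfg.n_background_genes, dtype=int),
    ]

    factors = rng.standard_normal((cfg.n_modules, n))
    lo, hi = cfg.loading_range
    loadings = np.where(labels > 0, rng.uniform(lo, hi, m), 0.0)
    eps = rng.standard_normal((m, n))
    Z = np.empty((m, n))
    for i in range(m):
        if labels[i] > 0:
            lam = loadings[i]
            Z[i] = lam * factors[labels[i] - 1] + cfg.noise_scale * np.sqrt(1 - lam**2) * eps[i]
        else:
            Z[i] = eps[i]

    # planted edges: pairs of above-median-loading genes within each module
    edges = []
    for mod in range(1, cfg.n_modules + 1):
        idx = np.nonzero(labels == mod)[0]
        med = np.median(loadings[idx])
        elig = idx[loadings[idx] >= med]
        max_edges = len(elig) * (len(elig) - 1) // 2
        if cfg.edges_per_module > max_edges:
            raise ValueError(
                f"module {mod}: requested {cfg.edges_per_module} edges, max {max_edges}"
            )
        chosen = set()
        while len(chosen) < cfg.edges_per_module:
            a, b = rng.choice(elig, size=2, replace=False)
            chosen.add((min(a, b), max(a, b)))
        for a, b in sorted(chosen):
            g = rng.standard_normal(n)
            if cfg.edge_form == "quadratic":
                g = (g**2 - 1) / np.sqrt(2)
            Z[a] += cfg.edge_boost * g
            Z[b] += cfg.edge_boost * g
            edges.append(_canon(genes[a], genes[b]))

    expr = pd.DataFrame(
        np.exp(cfg.mean_log + cfg.sd_log * Z), index=genes, columns=samples
    )
    trait = pd.Series(
        factors[cfg.trait_module - 1] + cfg.trait_noise * rng.standard_normal(n),
        index=samples,
        name="trait",
    )
    truth = SynthTruth(
        module_labels=pd.Series(labels, index=genes, name="module"),
        edges=EdgeList(edges, source="planted"),
        trait=trait,
        loadings=pd.Series(loadings, index=genes, name="loading"),
    )
    return SynthData(expr, trait, EdgeList(list(edges), source="prior"), truth, cfg)


def truth_eval(predicted, truth: SynthTruth) -> dict:
    """Score a prediction against the planted ground truth.

    ModuleAssignment -> {"ari": adjusted Rand index over shared genes}.
    GRNEdgeList -> {"precision", "recall", "n_predicted", "n_true"}
    against the planted edge set (precision NaN for an empty prediction).
    """
    from .coexpress import ModuleAssignment
    from .grn import GRNEdgeList

    if isinstance(predicted, ModuleAssignment):
        common = predicted.labels.index.intersection(truth.module_labels.index)
        if len(common) == 0:
            raise ValueError("no shared genes between prediction and truth")
        return {
            "ari": float(
                adjusted_rand_score(
                    truth.module_labels.loc[common], predicted.labels.loc[common]
                )
            )
        }
    if isinstance(predicted, GRNEdgeList):
        pred = predicted.as_set()
        true = truth.edges.as_set()
        known = {g for e in true for g in e}
        unknown = {g for e in pred for g in e} - set(truth.module_labels.index)
        if unknown:
            raise ValueError(f"predicted genes outside the truth namespace: {sorted(unknown)[:5]}")
        inter = len(pred & true)
        return {
            "precision": inter / len(pred) if pred else float("nan"),
            "recall": inter / len(true) if true else float("nan"),
            "n_predicted": len(pred),
            "n_true": len(true),
        }
    raise TypeError(f"cannot evaluate object of type {type(predicted).__name__}")
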