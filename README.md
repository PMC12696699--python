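# modgrn

Module-based gene regulatory network (GRN) inference from bulk RNA-seq
expression, for computational biologists who want to go from an FPKM-like
gene × sample matrix to a predicted regulatory network among the key genes
of a trait-associated coexpression module — plus a prognostic risk score
for the samples.

## What it does

The pipeline couples weighted coexpression analysis with a supervised
pair classifier:

1. **Preprocess.** Log transform `I_ij ← log(1 + I_ij)`, retain the most
   variable genes by median absolute deviation
   `mad_i = median_j |I_ij − median_j(I_ij)|`, and drop samples whose mean
   Euclidean distance to the rest of the cohort exceeds a threshold.
2. **Coexpression network.** Pearson correlation between gene rows, signed
   soft-threshold adjacency `a_ij = ((1 + cor_ij)/2)^β` with β chosen as the
   smallest power whose connectivity distribution fits a scale-free law
   (signed R² ≥ 0.85), and topological overlap

   `TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(K_i, K_j) + 1 − a_ij)`,
   `K_i = Σ_{u≠i} a_iu`.
3. **Modules and key genes.** Average-linkage clustering of `1 − TOM` with
   a static tree cut, minimum module size 30, module eigengenes (first
   principal component of the standardized member block), module–trait
   correlation, and key-gene screening by gene significance
   `GS_i = |cor(X_i, trait)| > 0.2` and module membership
   `MM_i = |cor(X_i, eigengene)| > 0.8`.
4. **Pair classification.** Prior-network edges among module genes are
   positives, sampled non-edges negatives; each pair becomes a 32×32 joint
   expression histogram; a small CNN (3×3 convolutions, 2×2 max-pooling,
   ReLU, dropout P = 0.25, sigmoid head, binary cross-entropy) maps the
   histogram to a regulatory probability, evaluated by K-fold
   cross-validation (accuracy, TPR, FPR, ROC/AUC).
5. **GRN and baselines.** All key-gene pairs are scored; scores above 0.9
   form the predicted network, compared against reference edge lists.
   Baselines: a random forest on concatenated expression vectors and a
   binned mutual-information score with a quantile cutoff.
6. **Prognosis.** `PI_j = Σ_i β_i I_ij` from supplied Cox coefficients,
   with samples above the PI of the per-gene-median profile labelled
   high-risk.

A latent-factor synthetic generator (`modgrn.synth`) plants modules, a
trait association, and a ground-truth edge set, so the whole pipeline is
testable without any external downloads.

## Worked example

```python
import modgrn as mg

data = mg.generate(mg.SynthConfig(seed=7))        # 400 genes x 200 samples
X = mg.log_transform(data.expression)

T = mg.tom(mg.signed_adjacency(mg.pearson_correlation(X), 6))
assign = mg.detect_modules(T, X, min_size=30)
print(mg.truth_eval(assign, data.truth))          # {'ari': 1.0}

genes = data.truth.module_labels.index[data.truth.module_labels > 0].tolist()
pairs, hists = mg.build_labeled_dataset(X, genes, data.prior, seed=7)
pairs = mg.kfold_split(pairs, K=5, seed=7)
report = mg.cross_validate(hists, pairs, mg.ModelConfig.compact(),
                           mg.TrainConfig(seed=7, epochs=20, batch_size=32))
print(round(report.auc, 3), round(report.accuracy, 3))   # 0.959 0.904
```

The ARI of 1.0 says the five planted coexpression modules were recovered
exactly; the pooled cross-validated AUC of 0.959 says the CNN separates
planted regulatory pairs from sampled non-edges almost perfectly, each
pair scored by a model that never saw it. On the same data the
random-forest baseline reaches AUC 0.953 and the mutual-information score
0.789. The `examples/` directory has one narrative script per capability
(preprocessing, modules/key genes, training, GRN prediction and coverage,
prognostic scoring); each prints its numbers with a line on what they
mean. A thin `modgrn` command mirrors the same steps for shell use.

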