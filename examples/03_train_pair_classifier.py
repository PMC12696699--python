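"""Train and cross-validate the histogram CNN pair classifier.

Positive pairs come from the planted prior network; negatives are sampled
non-edges. Each pair becomes a 32x32 joint-expression histogram, and a
small CNN is evaluated with 5-fold cross-validation: every pair is scored
exactly once by a model that never saw it.
"""

import modgrn as mg

data = mg.generate(mg.SynthConfig(seed=7))
X = mg.log_transform(data.expression)
truth = data.truth.module_labels
module_genes = truth.index[truth > 0].tolist()

pairset, hists = mg.build_labeled_dataset(X, module_genes, data.prior,
                                          neg_ratio=1.0, seed=7)
print(f"labeled pairs: {len(pairset)} ({pairset.labels.sum()} positive, "
      f"{(pairset.labels == 0).sum()} negative)")

pairset = mg.kfold_split(pairset, K=5, seed=7)
report = mg.cross_validate(
    hists, pairset,
    mg.ModelConfig.compact(),             # 8/16-filter conv blocks, dense 32
    mg.TrainConfig(seed=7, epochs=20, batch_size=32),
)
print("\nper-fold held-out metrics:")
print(report.per_fold.round(3).to_string(index=False))
print(f"\npooled: AUC={report.auc:.3f} accuracy={report.accuracy:.3f} "
      f"TPR={report.tpr:.3f} FPR={report.fpr:.3f}")

# The confidence histogram should pile correct predictions near 0 and 1 —
# the classifier is not merely right, it is confidently right.
print("\nconfidence histogram (bin start: correct / incorrect):")
for lo, ok, bad in zip(report.confidence_bins, report.confidence_correct,
                       report.confidence_incorrect):
    print(f"  {lo:.1f}: {ok:4d} / {bad:3d}")
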