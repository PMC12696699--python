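"""Preprocess a raw FPKM-like expression matrix.

Generates a small synthetic cohort, then applies the three preprocessing
steps: log(1+x) transform, retention of the most variable genes by median
absolute deviation (MAD), and removal of samples whose mean Euclidean
distance to the rest of the cohort is extreme.
"""

import modgrn as mg

data = mg.generate(mg.SynthConfig(seed=7, n_samples=100))
print(f"raw matrix: {data.expression.shape[0]} genes x {data.expression.shape[1]} samples")

X = mg.log_transform(data.expression)

X, gene_report = mg.mad_filter(X, mode="top_k", k_or_threshold=300)
print(f"MAD filter: kept the {gene_report.genes_out} most variable of "
      f"{gene_report.genes_in} genes "
      f"(lowest retained MAD = {gene_report.mad_per_gene.sort_values().iloc[-300]:.3f})")

X, sample_report = mg.remove_outlier_samples(X, alpha_sd=3.0)
print(f"outlier screen: {sample_report.samples_in} -> {sample_report.samples_out} samples "
      f"(threshold alpha = {sample_report.params['alpha']:.2f} on the mean-distance statistic)")

# The retained matrix is what the coexpression stage consumes; genes dropped
# here are the near-constant ones that carry no coexpression signal.
print(f"final matrix: {X.shape[0]} genes x {X.shape[1]} samples")
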