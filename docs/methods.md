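# Methods

## Overview

`modgrn` infers a gene regulatory network in two stages. The first stage is
unsupervised: a weighted coexpression network is built from a gene × sample
expression matrix, clustered into modules, and the module most correlated
with a sample trait is mined for key genes. The second stage is supervised:
known interactions from a prior network (e.g. a STRING export restricted to
the module) label gene pairs, each pair is summarized as a 32×32 joint
expression histogram, and a convolutional network learns to classify pairs
as regulatory or not. The trained classifier then scores all key-gene pairs
and the high-confidence edges form the predicted GRN.

## Preprocessing

Raw values are assumed non-negative and FPKM-like. The pipeline applies, in
order: `log(1+x)` (natural log by default; base 2 differs only by a
monotone scale), a median-absolute-deviation gene filter, and Euclidean
sample-outlier removal.

The MAD filter *retains* the highest-MAD genes (default: top 15,000 in
`top_k` mode). Genes with near-zero MAD are near-constant and carry no
coexpression signal, so retention of the variable side is the only reading
consistent with downstream use; an `absolute` mode with an explicit
retained-side flag covers the alternative. Sample outliers are flagged by
the mean Euclidean distance to all other samples; the default threshold is
mean + 3·sd of that statistic (a z-score variant is available). The
statistic, not a single linkage branch, makes the rule permutation
-equivariant and cheap at thousands of samples.

## Coexpression network

* **Correlation.** Pearson between gene rows; zero-variance genes are a
  hard error (filter first).
* **Adjacency.** Signed: `a_ij = ((1+cor_ij)/2)^β`. Strong negative
  correlation maps near 0, strong positive near 1.
* **Soft-threshold choice.** For each candidate β (default 1–20), the
  connectivity values `K_i = Σ_{u≠i} a_iu` are split into 10 equal-width
  bins; ordinary regression of log10(bin frequency) on log10(bin mean K)
  gives the fit index `−sign(slope)·R²`. The chosen β is the smallest with
  fit ≥ 0.85 (cut configurable; 0.8 is a common alternative), else the
  argmax with a warning. Fewer than 3 usable bins, or a degenerate
  regression, records the fit as missing rather than 0. On small synthetic
  instances (hundreds of genes) the fit rarely reaches the cut — scale-free
  behaviour is an asymptotic property of large networks — so the examples
  operate at the conventional β = 6.
* **Topological overlap.** `TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) /
  (min(K_i,K_j) + 1 − a_ij)` with the adjacency diagonal excluded from all
  sums (this keeps TOM ≤ 1) and TOM diagonal set to 1. The matrix form
  `A₀A₀ + A₀` with zeroed diagonal is algebraically identical to the
  explicit triple loop, which the tests verify to 1e−10.

## Module detection

Average-linkage hierarchical clustering on `1 − TOM`. The tree is cut
statically; when no height is given, candidate cuts between successive
merge heights are scanned and the cut revealing the most clusters of at
least `min_size` (default 30) members wins, highest cut on ties. A fixed
fraction of the maximum merge height was tried first and proved brittle:
the informative height range shifts with gene count and noise level,
whereas the count-maximizing cut tracks it automatically while remaining
deterministic. Loose static cuts also absorb unconnected genes into
otherwise clean clusters, so members whose correlation with their cluster
eigengene falls below `kme_prune` (default 0.3) are relabelled grey before
size filtering. Modules whose eigengenes correlate above `merge_cut`
(default 0.9) are merged iteratively. Final labels are integers 1..M by
descending size, 0 reserved for grey. A full dynamic-hybrid tree cut is
intentionally out of scope.

The module eigengene is the first right singular vector of the z-scored
member block (unit norm over samples), sign-oriented so its correlation
with the mean member profile is non-negative. Module–trait correlation is
Pearson with the two-sided t-approximation p-value and no multiplicity
correction (one test per module, typically < 20 modules).

Key genes: within the chosen module (default: the top trait-correlated
one), candidates need module membership MM > 0.8 and gene significance
GS > 0.2; the top 10 by GS are returned, ties broken by MM then gene id.
An empty candidate set is a warning, not an error.

## Pair data

Pairs are unordered; the lexicographically smaller gene id is stored first
so features are deterministic. Positives are prior-network edges among the
module genes; negatives are uniformly sampled non-edges from the same
universe (rejection sampling, with exact enumeration when the feasible
space is small), default 1:1 with positives — balance keeps the
classifier's confidence distribution symmetric between classes. The
32×32 histogram bins each gene's range [min, max] into 32 equal
subintervals, `floor(32·(x−min)/(max−min))` clipped so the maximum lands in
the last bin; a constant gene degenerates to bin 0 with a warning. Counts
are stored raw; the model wrapper standardizes its input internally (a
single global mean/sd learned from the training histograms), which is a
conditioning choice, not a change to the stored counts. K-fold splits are
stratified by label (fold sizes differ by ≤ 1, label ratio preserved
within one item).

## The CNN

Architecture: repeated blocks of 3×3 same-padding convolution → ReLU → 2×2
max-pool, then flatten → dropout → dense ReLU → dropout → single sigmoid
unit. Dropout uses inverted scaling — units are zeroed with probability
P = 0.25 and survivors multiplied by 1/(1−P) — so inference needs no
rescaling; the tests check the expectation Monte-Carlo. Training minimizes
binary cross-entropy (numerically as `log(1+e^z) − y·z` on logits) with
Adam at 1e−3, batch 32–64, fixed seed; forward and backward passes are
written directly on NumPy arrays and verified against central finite
differences.

The default configuration is three blocks (32/64/128 filters) with a
256-unit dense layer (~0.6 M parameters). `ModelConfig.compact()` (8/16
filters, dense 32, ~35 k parameters) is the variant used throughout the
examples, tests and acceptance runs: with labeled sets of a few hundred
pairs the larger net gains nothing, and the compact one trains in seconds
per fold on a single CPU. Cross-validation trains one fresh model per fold
(seed offset by fold index) and pools the held-out scores, so each pair is
scored exactly once by a model that never saw it; the pooled ROC/AUC is
the headline number, with a per-fold table attached.

`evaluate` reports confusion counts at a 0.5 threshold (the GRN stage
applies its own, stricter 0.9 cutoff — the two thresholds are distinct
decisions), the full-sweep ROC with trapezoid AUC (equal to the scaled
Mann–Whitney U statistic, which the tests assert), and a 10-bin confidence
histogram of correct vs incorrect predictions. One-class label vectors
leave the undefined rate and the AUC as NaN rather than a silent 0.

## GRN, coverage, baselines

Scores strictly above the cutoff (default 0.9) are retained, sorted
descending. Coverage counts undirected set intersections with each
reference edge list and with their union. `top_regulators` ranks the
candidate partners of one target gene with a fixed (target, candidate)
histogram orientation so that expression-identical candidates receive
identical scores.

Random-forest baseline: per pair, the two expression vectors concatenated
(500 trees, seeded, same folds and metrics as the CNN). Mutual-information
baseline: plug-in estimate on an 8×8 equal-width binned joint distribution
in nats; pairs above a score quantile (default 0.95) form the network.
Constant genes yield NaN scores rather than fake zeros.

## Prognostic index

`PI_j = Σ_i β_i I_ij` with coefficients supplied by the caller — Cox
fitting itself is delegated to standard survival libraries and is outside
the tested core. The classification threshold is the PI of the
per-gene-median pseudo-sample, `Σ_i β_i · median_j(I_ij)`; the alternative
reading (median of the per-sample PI values) is available via
`rule="median_pi"`. Samples strictly above the threshold are "high".
Rescaling all coefficients by a positive constant and recomputing the
threshold leaves the grouping invariant.

## Synthetic data

A Gaussian latent-factor model: module m has factor `f_m ~ N(0,1)` per
sample; gene i in module m has latent profile
`z_i = λ_i f_m + s·sqrt(1−λ_i²) ε_i` with loading `λ_i ~ U(0.6, 0.95)` and
noise scale `s = 0.6`; background genes are pure noise. Planted edges
connect above-median-loading genes within a module (80 per module by
default, ~400 positives → ~800 labeled pairs at 1:1 balance); each edge
adds a private shared component `δ·g_e`, `δ = 0.6`, to both endpoints, so
edge pairs carry joint dependence beyond the module baseline — the signal
the pair classifier must find. A quadratic edge form is available to give
the mutual-information baseline a nonlinear target. The trait is the
designated module's factor plus noise (sd 0.5). Latent profiles map to a
non-negative FPKM-like scale via `exp(2 + 0.8·z)`, so preprocessing is
exercised end to end. Everything is a deterministic function of (config,
seed).

The noise scale 0.6 was set so that module tightness resembles a real
trait-associated module: many members with eigengene correlation above
0.8, as the key-gene screen presumes. The per-edge components make hub
genes noisier than their loadings alone imply — a realistic feature (hubs
integrate many signals) with the consequence that hubs themselves tend to
fail the MM screen on this fixture.

What the generator does *not* emulate: count noise and
mean–variance coupling of real RNA-seq, batch structure, directed or
signed regulation, and realistic degree distributions in the planted edge
set. Passing tests therefore demonstrate correctness of the machinery and
learnability under the stated model, not performance on real cohorts.

## Problem sizes and numerics

Examples, tests and the acceptance script run the full study conditions of
the generator: 5 modules × 60 genes + 100 background genes, 200 samples,
~800 labeled pairs, 5-fold cross-validation with the compact model at 20
epochs — sizes at which every stage is exact or well-conditioned and the
whole pipeline completes in a few minutes on one CPU. Matrix TOM is
checked against a literal triple loop at 1e−10; Pearson and PI arithmetic
at 1e−12; AUC against the U statistic at 1e−9. Degenerate inputs
(constant genes, one-class labels, empty candidate sets, all-equal
connectivity) are reported as errors, warnings or NaN as documented above,
never silently coerced.

## Known limitations

* The static tree cut, even with the count-maximizing height, is cruder
  than dynamic-hybrid cutting on real dendrograms with nested modules.
* The plug-in MI estimator is biased upward at small sample counts; no
  bias correction is applied (the quantile cutoff is rank-based and
  unaffected).
* The scale-free fit index is meaningful only for networks of thousands of
  genes; on small fixtures the β choice should be made by convention.
* Pair classification treats edges as undirected and ignores regulation
  sign/type.
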