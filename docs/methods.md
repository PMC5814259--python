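# Methods

## Model

`embryoscore` treats developmental staging as a five-class classification
problem over ESC, iPSC, EPC, ASC and AC transcriptomes, solved by an
ensemble of directional one-vs-one binary networks. Each ordered class
pair (p, n) has its own dense network trained only on samples of those
two classes, with target 1 for p and 0 for n; for K classes there are
K·(K−1) networks (20 for the canonical five). The ensemble vote for class
i is the sum of the sigmoid outputs of the K−1 networks in which i is
positive, so votes lie in [0, K−1]. Training both directions of every
pair means each class's vote aggregates networks that were all optimized
*for* that class, and no thresholding is applied before summation — votes
stay soft, which is what lets the score interpolate between classes.

The Embryonic Score is the vote-mass-weighted mean of fixed per-class
degrees of embryonic development,

ES = Σᵢ Classᵢ·wᵢ / Σᵢ Classᵢ,  w = (ESC 1.0, iPSC 0.9, EPC 0.7, ASC 0.5, AC 0.0),

which is scale-invariant in the votes, bounded by [min w, max w], equals
1 for a pure-ESC vote and 0 for a pure-AC vote, and is monotone under
moving vote mass toward higher-weight classes. An all-zero vote vector
has no defined score and raises. Prediction is the argmax vote with exact
ties broken by the canonical class order (ESC first) and logged.

### Assumptions

- Class identity is encoded in a broad multivariate expression signature,
  not a handful of genes; networks see the full gene vector.
- iPSC and ESC transcriptomes are nearly identical; the model is allowed
  to confuse them and the score treats them almost equally (0.9 vs 1.0).
- Inputs are non-negative expression intensities on a common scale,
  enforced by frozen quantile normalization rather than assumed.

## Preprocessing

Probe-to-gene aggregation uses the geometric mean of a gene's probes
(exp of the mean log signal), which is undefined for non-positive values:
the default is a hard error, with an opt-in pseudo-floor (clip to a
configured value, logged) for matrices containing zeros. Background
masking floors (or drops) values strictly under a threshold, default 130
relative fluorescence units — the nonspecific-signal level of BeadArray
intensities.

Quantile normalization is *frozen*: fitting records the rank-wise mean of
the sorted training columns as the target quantiles, and transforming any
later sample maps its values onto those quantiles by rank. Ties receive
the mean of the tied target quantiles (the common "average ties"
dialect), which preserves equalities and keeps the transform idempotent.
Genes missing at prediction time raise by default; median imputation is
opt-in because silently imputing biases votes. Normalization operates on
the scale given; an optional log2(x+1) pre-transform lets RNA-seq counts
flow through a reference fitted on array intensities. The implementation
is checked in the test suite against limma's `normalizeQuantiles` as an
independent oracle.

## Networks and training

Networks are plain dense feed-forward models implemented on numpy:
hidden layers with ReLU/sigmoid/tanh activation, inverted dropout after
each hidden activation, L2 weight penalty, a sigmoid (binary) or softmax
(multiclass) output, cross-entropy loss, and minibatch Adam. Ensemble
members share the multiclass optimum: 2 layers × 200 neurons, ReLU,
dropout 0.2, L2 0.03, 200 epochs. Batch size 64 and Adam's default
learning rate 1e-3 are package choices (unspecified upstream). Per-member
seeds are derived as `base_seed XOR pair_index` and recorded, making
ensembles bit-reproducible.

Numerical choices: weights use He initialization; inputs are
standardized per feature inside `fit` (mean/SD stored with the model and
re-applied at inference). Without this, expression-scale inputs (log2
intensities around 8) saturate the output nonlinearity at initialization
and gradients vanish; standardization is an internal conditioning step,
not part of the public preprocessing contract.

Baseline families wrap scikit-learn and xgboost: kNN (k 5–20, uniform or
distance weights, Manhattan/Euclidean/Minkowski-3 metrics), logistic
regression preceded by whitened PCA (100–500 components, C 0.1–100), SVM
(linear/sigmoid/3rd-degree-poly/RBF kernels, C 0.1–100), gradient
boosting (10–100 trees, depth 3–8, subsample 0.5–1.0, gamma 0.5–1,
min child weight 1–5, learning rate 0.005–0.05) and the multiclass DNN
(2–4 layers, 100–500 neurons, ReLU/sigmoid/tanh, L2 0.01–0.05, dropout
0–0.5). Concrete training points are validated against these ranges.
SVM probabilities come from the standard sigmoid calibration of decision
values. No class reweighting is applied; balance is the splitter's job.

## Evaluation

`make_group_stratified_folds` assigns whole source datasets (groups) to k
folds greedily, largest group first with seeded random tie-breaks, each
into the fold minimizing the resulting sum of squared per-class counts.
Groups are never split; fewer groups than folds is an error, and a class
confined to one group triggers a warning because it is untestable in some
folds. `nested_cv` holds out one group-fold at a time, tunes
hyperparameters inside the remaining groups with a Tree-of-Parzen-
Estimators sampler (good/bad split at the 25% quantile of the objective,
Gaussian-kernel Parzen densities per numeric parameter, smoothed counts
for categoricals, best-of-24 candidates by density ratio; parameters
treated independently), scores each candidate by mean inner
group-aware-fold macro-F1, refits the chosen point and reports the
held-out ("Ext. validation") score plus inner-loop Training and
Int. validation scores. Both loops default to 3 folds; the TPE budget
defaults to 50 evaluations per outer fold and is configurable.
`naive_cv` uses the same scoring machinery with class-stratified folds
that ignore groups — provided solely to demonstrate how batch leakage
inflates scores. Macro-F1 treats a class absent from both truth and
prediction as F1 = 0; pooled-confusion macro-F1 is also provided because
pooling tests every sample exactly once even when single folds lack a
class.

## Feature importance

For networks, gene importance is the magnitude propagated to the output:
row sums of |W₁|·|W₂|·…·|W_out| with biases, dropout and activations
ignored. Ensemble importance averages per-member scores after
normalizing each member's scores to sum 1, so no single network's weight
scale dominates (an explicit design choice; aggregation across members
is otherwise underdetermined). For boosted trees, the f-score counts how
many times a feature splits a tree. Ranks use min-rank ties, logged.
Because inputs are standardized inside the networks, importance reflects
how class-structured a gene's variation is, not its raw amplitude.

## Synthetic corpora

The generator emulates a curated multi-dataset five-class microarray
corpus at desk scale. On log2 scale each value is base (8.0) + a
per-class, per-gene offset (SD `class_signal_sd`, default 1.0) + a
per-group, per-gene batch offset (SD `batch_sd`, default 0.5) + sample
noise (SD `noise_sd`, default 0.3); values are exponentiated to linear
intensities so they traverse the same preprocessing as real data. The
iPSC signature is `esc_ipsc_similarity` (default 0.95) of the ESC
signature plus its own residual, reflecting how close reprogrammed cells
are to ESCs. Defaults use 2,000 genes, 40 samples per class and 12 source
datasets. Groups are *class-linked* — each synthetic dataset contributes
one class — because that confounding of batch with biology is what real
series exhibit and is the mechanism behind naive-CV overestimation;
every class spans at least two datasets so it remains testable under
group-aware folds. Markers with chosen per-class log2 means can be
planted (overriding drawn means) as recovery targets for the importance
methods, e.g. an adult-high/embryonic-low gene and its embryonic-high
mirror. A differentiation series interpolates the true signature linearly
from ESC to AC across steps, with noise, for testing monotone score
decline.

What the simulator does **not** model: platform-specific probe effects,
intensity-dependent (non-additive) batch distortions, count noise of
RNA-seq, correlated gene modules, or class imbalance. Passing the
recovery suites therefore shows the machinery is correct and the
phenomena (batch leakage, ESC/iPSC confusion, marker recovery, score
decline) are reproduced under controlled conditions — not that any
particular accuracy will transfer to real corpora.

## Problem sizes and defaults used in the checks

The test and acceptance runs use deliberately scaled-down settings,
chosen as the package's own desk-scale study conditions: ensemble members
of 2 × 50 neurons trained 50 epochs for corpus-level recovery (2,000
genes, 40 samples/class, 12 groups), 2 × 30 neurons × 200 epochs for
marker-recovery replicates on 400–500-gene corpora, and kNN for the
cross-validation contrast (class signal SD 0.4 vs batch SD 0.8). The
acceptance script evaluates the two analytic anchors of the Embryonic
Score (pure-ESC → 1.0, pure-AC → 0.0) and, for context, the mean scores
of ESC and AC samples of a freshly trained 600-gene ensemble.

## Known limitations

- Trained-network vote levels for classes far from a sample's true class
  are uncalibrated (networks are queried outside their training pair), so
  absolute E scores compress toward the middle of the scale; orderings
  and trends are the reliable readout.
- The TPE sampler treats parameters independently and can stick to one
  categorical arm at small budgets; it is a hyperparameter search aid,
  not a contribution of the package.
- Group-stratified folding is heuristic (greedy); with class-pure groups
  and few groups per class, some folds cannot test every class — the
  pooled confusion matrix is the recommended summary in that regime.
- The narrative convention that progenitors sit at 0.5 and adult stem
  cells at 0.7 on the axis appears in some descriptions of the EFT range;
  this package uses w_EPC = 0.7 > w_ASC = 0.5, i.e. progenitors are the
  more embryonic of the two.
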