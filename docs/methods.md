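# Methods

## Model

The classifier couples three stages, each fitted per train split.

**Tree-generated feature graphs.** One gradient-boosted tree ensemble
(XGBoost, 100 trees by default, library defaults otherwise; all extra
hyperparameters are echoed in the run log) is trained per modality. The
selected feature set is the union of split features across all trees, in
first-appearance order over `(tree, node)` — this fixed order makes the
adjacency layout reproducible. Edges connect *direct* parent–child split
pairs only: a split node contributes one undirected edge per split-node
child, edges into leaves contribute nothing, and a node splitting the same
feature as its parent adds only the self-pair. Self-loops are added for
every selected feature, and edge counts include them once each, so the
edge-to-node ratio `m = |E|/p*` of a self-loops-only graph is exactly 1.
A transitive reading — connecting every pair of split features on a common
root-to-leaf path — is available behind `build_feature_graph(...,
path_closure=True)` but is not the default: the direct parent–child pair is
the local interaction the tree structure actually encodes, and the closure
makes graphs substantially denser. Substituting a random forest for the
booster (`motgnn_rf`) changes only the ensemble; parser and graph builder
are shared.

**Graph-embedded encoders.** Each encoder's first layer has width `p*` and
computes `ReLU(X* (W_in ⊙ Ã) + b_in)`. The mask is applied inside every
forward pass (not by one-time zero initialisation), and the weight
gradient is masked likewise, so masked positions are inert under
optimisation: perturbing them changes no prediction, exactly. `b_in` is a
length-`p*` vector broadcast over samples — a per-sample bias would be
untrainable for unseen samples. It is initialised to 0.1: inputs are
[0,1]-scaled and therefore non-negative, and a node whose mask row is a
lone self-loop with a negative initial weight would otherwise be a
permanently dead ReLU unit (zero output, zero gradient). The embedding
`Z_i` is the output of the last hidden layer: the graph-embedded layer
followed by `depth` dense blocks (affine → batch norm → ReLU → dropout)
of `width` units.

**Fusion and head.** Embeddings are concatenated in modality order and
passed through one dense block of `width` units and a 2-unit softmax head.
The rows of the first fusion weight matrix are partitioned by source
modality; these blocks are the `W_{Zi↔f}` used for graph importance.
Training uses binary cross-entropy on the positive-class probability —
with a 2-unit softmax this is mathematically identical to sigmoid + BCE —
plus `λ Σ w²` over dense weights (biases and batch-norm parameters are not
decayed; for the masked layer only unmasked entries are penalised).

## Tunable parameters

| parameter | default | notes |
|---|---|---|
| `n_trees` | 100 | trees per modality ensemble |
| `learning_rate` | 1e-4 | Adam step size; grid 1e-3/5e-4/1e-4 |
| `batch_size` | 16 | |
| `epochs` | 500 | upper bound; early stopping usually halts far earlier |
| `dropout` | 0.5 | after each hidden block |
| `l2_lambda` | 0.01 | weight-decay coefficient |
| `patience`, `min_delta` | 10, 1e-3 | early stopping on validation BCE |
| `depth`, `width` | 1, 64 | dense blocks per encoder; units per layer |

Depth/width sit mid-grid (1–3 layers, 32–128 units): one dense block per
encoder plus one fusion block keeps the parameter count proportionate to
the few hundred training samples these models see. The grid's smallest
learning rate is the default, but the synthetic-data experiments in the
test suite and `scripts/acceptance.py` use 1e-3 (also a grid value): at
1e-4 early stopping halts before the fusion weights move appreciably from
their symmetric initialisation, which flattens the relative graph
importances on desk-scale data.

## Training loop

Mini-batch Adam (β₁=0.9, β₂=0.999) with seeded batch shuffling. Batch
normalisation precedes ReLU inside each dense block; dropout follows.
After each epoch the batch-norm inference statistics are recomputed in one
dropout-free full pass over the training split ("precise" recalibration).
This matters: statistics accumulated during training see dropout-perturbed
activations whose variance exceeds that of inference-time activations, and
on small networks the mismatch inflates validation loss enough to trip
early stopping mid-training. Early stopping requires the validation BCE to
improve on the best value by more than `min_delta`; after `patience`
consecutive non-improving epochs training halts and the best-validation
weights (including batch-norm statistics) are restored.

One seed drives the split, the ensembles, weight initialisation, batch
shuffling and dropout (independent child generators via `SeedSequence`),
and all computation is single-threaded NumPy, so two runs with the same
seed produce byte-identical outputs.

## Synthetic data

The generator emulates three heterogeneous modalities on shared samples:
beta-mixture *bimodal* values (methylation-like), exponential
*right-skewed* values (expression-like), and *sparse* values with a point
mass at zero (miRNA-like). Informative features receive a between-class
mean shift of `effect_size` before additive Gaussian noise (`noise_sd`)
and per-feature min–max scaling; the planted columns are spread at random
positions. The positive count is exactly `round(n · class_ratio)` (half
up). The two-sample t-statistic of a planted feature is invariant to the
per-feature affine scaling and its within-class variance is unchanged by
the shift, so increasing `effect_size` at a fixed seed cannot decrease
any planted feature's |t|.

Default study conditions for the recovery experiments: 200:200:80
features (a ~10× scale-down of the 2,000:2,000:420 feature ratio typical
of processed methylation/mRNA/miRNA panels), 10% informative features,
`effect_size` 1.0–1.5, `noise_sd` 0.5, 240–332 samples with class ratios
from balanced to ~3:1. What passing these tests shows: the pipeline
recovers planted univariate mean-shift signal, attributes it to the
correct modality, and does not hallucinate signal under label permutation.
What they do not show: behaviour under correlated feature blocks, batch
effects, missing data, or nonlinear/epistatic signal — none of which the
generator emulates.

## Evaluation protocol

Repeated stratified 60/20/20 splits (default 20 repeats; repeat `r` is
seeded `base_seed + r`). Within each class, subset sizes use floor
allocation with largest-remainder rounding (ties resolved in
train/val/test order), so the three subsets partition the samples exactly.
Min–max normalisation is fitted on the training split and applied clipped
to [0,1] elsewhere; a `normalize_on_train=False` flag restores
whole-dataset scaling for fidelity comparisons, at the cost of mild
leakage. Graphs are rebuilt per split from the training rows only.
Metrics: accuracy at threshold 0.5 (configurable), rank-based ROC-AUC with
tied scores averaged, and F1 = 2PR/(P+R) defined as 0 when P+R = 0.
Aggregates report mean, SD (ddof 1) and the normal-approximation 95% CI
`mean ± 1.96·SD/√R`.

## Interpretability

IF sums *absolute* masked input weights — signed sums could cancel — and
is computed on the effective (masked) weights, so masked positions
contribute exactly 0. Scaling `W_in` by `c > 0` scales every IF by `c`;
IF values are therefore comparable within a trained model, not across
models. Cross-modality aggregation sums scores of identically named
features; omics name spaces are usually disjoint, so the combined ranking
is normally just the concatenation, and per-modality reports are the
primary output. RIG is invariant to a common rescaling of all fusion
blocks and errors out if every fusion weight is zero ("degenerate
fusion"). Rankings order by score descending with ties broken by name
ascending, so output is deterministic.

## Numerical choices and degenerate inputs

Probabilities are clipped to [1e-7, 1−1e-7] inside the loss; training
gradients are taken through logits directly, so no clipping artefacts
enter optimisation. Batch-norm ε is 1e-5; Adam ε is 1e-8. Constant
training features normalise to 0. An ensemble whose trees never split
raises "empty graph" rather than producing an unusable model. A training
or validation subset missing a class is rejected up front. Softmax rows
sum to 1 within 1e-9.

## Known limitations

Binary classification only; three modalities are assumed by the fusion
layout (the encoders generalise, the CLI does not). The NumPy training
loop is single-threaded by design — bit-reproducibility over throughput —
and is sized for the few-hundred-sample, few-hundred-feature regime. No
hyperparameter search automation is included; the grid above is documented
and individual values are configurable.
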