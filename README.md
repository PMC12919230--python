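# motgnn

Binary disease classification from multi-omics data — DNA methylation,
mRNA expression and miRNA expression measured on the same samples — with
supervised, tree-generated feature graphs, graph-embedded neural encoders
and built-in interpretability. The package is aimed at computational
biologists who want a classifier for the "small n, large p" regime that
also reports *which* features and *which* omics layer drove a prediction.

## The method

For each omics matrix `X_i ∈ R^{n×p_i}` and binary labels `Y`:

1. **Tree-guided feature selection and graph construction.** A gradient-
   boosted tree ensemble (XGBoost; optionally a random forest for the
   `motgnn_rf` ablation) is trained to predict `Y` from `X_i`. The union of
   features used in any split defines the selected set (size `p*_i`), and
   every direct parent–child pair of split features becomes an undirected
   edge. Self-loops are added to give the augmented adjacency `Ã_i`.
2. **Graph-embedded encoding.** A per-modality encoder whose first hidden
   layer has width `p*_i` and weight matrix `W_in` masked element-wise by
   the graph:

   `Z_1 = ReLU( X*_i (W_in ⊙ Ã_i) + b_in )`

   so only graph-supported connections are ever active, followed by dense
   layers with batch normalisation and dropout.
3. **Fusion and classification.** The modality embeddings are concatenated,
   `Z = Z_1 | Z_2 | Z_3`, and passed through a feedforward classifier with
   a 2-unit softmax head. Training minimises binary cross-entropy plus an
   L2 penalty `λ Σ w²` with mini-batch Adam and early stopping on
   validation loss.
4. **Interpretability.** Feature importance
   `IF_j = Σ_u |W_in[j,u]| · 1(Ã[j,u]=1)` ranks biomarkers per modality;
   relative graph importance `RIG_i = ‖W_{Zi↔f}‖₁ / Σ_k ‖W_{Zk↔f}‖₁`
   (L1 norms of the fusion weight blocks) quantifies each omics layer's
   contribution and sums to 1.

Evaluation uses repeated stratified 60/20/20 train/validation/test splits;
normalisation, feature selection and graph construction are fitted on each
training split only, so no label information leaks into the test fold.

## Worked example

```python
from motgnn import (SyntheticConfig, SplitScheme, TrainingConfig, run_experiment)

cfg = SyntheticConfig(
    n_samples=240, class_ratio=0.25,            # 3:1 imbalance
    dims=(200, 200, 80),                        # meth / mRNA / miRNA features
    informative_per_modality=(20, 20, 8),
    effect_size=1.5, noise_sd=0.5, seed=11,
)
result = run_experiment(
    synthetic=cfg,
    train_cfg=TrainingConfig(seed=11, learning_rate=1e-3),
    scheme=SplitScheme(n_repeats=5, base_seed=11),
)
agg = result.summary.iloc[-1]
print(f"accuracy={agg['accuracy']:.3f} roc_auc={agg['roc_auc']:.3f} f1={agg['f1']:.3f}")
print("RIG:", [round(v, 3) for v in result.mean_graph_importance])
```

prints

```
accuracy=1.000 roc_auc=1.000 f1=1.000
RIG: [0.338, 0.334, 0.328]
```

On this strongly separable synthetic cohort the classifier is perfect on
every held-out test fold despite the 3:1 class imbalance (an all-majority
classifier would score F1 = 0), and the relative graph importances are
near-uniform because all three modalities carry planted signal. When the
signal is planted in a single modality, that modality's RIG rises and its
planted features dominate the IF ranking (see `tests/test_acceptance.py`).

The same pipeline runs from the shell on delimited files:

```bash
motgnn simulate --outdir data --seed 4
motgnn run --meth data/meth.tsv --mrna data/mrna.tsv --mirna data/mirna.tsv \
           --labels data/labels.tsv --outdir results --repeats 20 --seed 42
motgnn explain --checkpoint ckpt/ --top-k 30
```

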