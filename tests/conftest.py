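"""Shared fixtures: a small synthetic dataset and one fully trained model,
built once per session and reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from motgnn import (
    EnsembleSpec,
    SplitScheme,
    SyntheticConfig,
    TrainingConfig,
    build_feature_graph,
    fit_tree_ensemble,
    generate_multiomics,
    stratified_splits,
    train_motgnn,
)


@pytest.fixture(scope="session")
def small_dataset():
    """Three modalities, 200 samples, planted signal in every modality."""
    cfg = SyntheticConfig(
        n_samples=200,
        class_ratio=0.5,
        dims=(100, 100, 40),
        informative_per_modality=(10, 10, 5),
        effect_size=1.0,
        noise_sd=0.5,
        seed=3,
    )
    return generate_multiomics(cfg)


@pytest.fixture(scope="session")
def trained_pipeline(small_dataset):
    """Graphs built on the training split plus a trained model."""
    X, y, truth = small_dataset
    train_idx, val_idx, test_idx = stratified_splits(
        y, SplitScheme(n_repeats=1, base_seed=7)
    )[0]
    graphs = []
    for m in X:
        records = fit_tree_ensemble(
            m.subset_rows(train_idx), y.labels[train_idx], EnsembleSpec(seed=7)
        )
        graphs.append(build_feature_graph(records, m.modality_id, m))
    cfg = TrainingConfig(seed=7, learning_rate=1e-3)
    model, history = train_motgnn(X, y, graphs, cfg, train_idx, val_idx)
    return {
        "X": X,
        "y": y,
        "truth": truth,
        "graphs": graphs,
        "model": model,
        "history": history,
        "cfg": cfg,
        "splits": (train_idx, val_idx, test_idx),
    }
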