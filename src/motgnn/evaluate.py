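"""Repeated stratified evaluation of the full pipeline.

Each repetition draws a stratified 60/20/20 train/validation/test split,
fits the per-modality tree ensembles and feature graphs on the training
split only, trains the classifier with early stopping on the validation
split, and scores accuracy, ROC-AUC and F1 on the held-out test split.
Summary statistics (mean, SD, normal-approximation 95% CI) aggregate the
repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import confusion_matrix, roc_auc_score

from .datatypes import LabelVector, OmicsMatrix
from .interpret import (
    ImportanceReport,
    build_report,
    write_feature_importance,
    write_graph_importance,
)
from .nn import TrainingConfig, predict_positive_proba, train_motgnn
from .synthetic import SyntheticConfig, generate_multiomics, minmax_normalize
from .tree_graph import (
    EnsembleSpec,
    FeatureGraph,
    build_feature_graph,
    fit_tree_ensemble,
    graph_stats,
    write_graph_stats,
)


@dataclass
class SplitScheme:
    """Stratified repeated splitting: fractions per subset, number of
    repeats, and the base seed (repeat r uses base_seed + r)."""

    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    n_repeats: int = 20
    base_seed: int = 0

    def validate(self) -> None:
        if len(self.fractions) != 3 or any(f <= 0 for f in self.fractions):
            raise ValueError("fractions must be three positive values")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be positive")


@dataclass
class MetricsRecord:
    repeat_index: int
    accuracy: float
    roc_auc: float
    f1: float
    tp: int
    fp: int
    tn: int
    fn: int


def _largest_remainder(n: int, fractions: tuple[float, ...]) -> list[int]:
    """Integer allocation of n items to len(fractions) bins, floors first,
    remaining items to the largest fractional remainders (ties broken by
    bin order)."""
    exact = [n * f for f in fractions]
    counts = [int(np.floor(e)) for e in exact]
    leftover = n - sum(counts)
    order = sorted(range(len(fractions)), key=lambda i: (-(exact[i] - counts[i]), i))
    for i in order[:leftover]:
        counts[i] += 1
    return counts


def stratified_splits(
    y: LabelVector, scheme: SplitScheme
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per repeat, a disjoint (train, val, test) partition of all sample
    indices, allocated per class by largest-remainder rounding."""
    scheme.validate()
    labels = y.labels
    for c in (0, 1):
        if int((labels == c).sum()) < 5:
            raise ValueError(f"class {c} stratum too small: need at least 5 samples")
    splits = []
    for r in range(scheme.n_repeats):
        rng = np.random.default_rng(scheme.base_seed + r)
        parts: list[list[int]] = [[], [], []]
        for c in (0, 1):
            idx = np.flatnonzero(labels == c)
            idx = rng.permutation(idx)
            counts = _largest_remainder(len(idx), scheme.fractions)
            start = 0
            for part, count in zip(parts, counts):
                part.extend(int(i) for i in idx[start : start + count])
                start += count
        splits.append(tuple(np.sort(np.array(p, dtype=int)) for p in parts))
    return splits


def compute_metrics(
    y_true: np.ndarray,
    prob_positive: np.ndarray,
    threshold: float = 0.5,
    repeat_index: int = 0,
) -> MetricsRecord:
    """Accuracy at the threshold, rank-based ROC-AUC (ties averaged), and
    F1 = 2PR/(P+R) with the 0/0 case defined as 0."""
    y_true = np.asarray(y_true, dtype=int)
    prob_positive = np.asarray(prob_positive, dtype=float)
    if (prob_positive < 0).any() or (prob_positive > 1).any():
        raise ValueError("probabilities must lie in [0, 1]")
    if len(np.unique(y_true)) < 2:
        raise ValueError("ROC-AUC undefined: y_true contains a single class")
    y_pred = (prob_positive >= threshold).astype(int)
    tn, fp, fn, tp = confusion_matrix(y_true, y_pred, labels=[0, 1]).ravel()
    accuracy = (tp + tn) / len(y_true)
    denom = 2 * tp + fp + fn
    f1 = 2 * tp / denom if denom > 0 else 0.0
    return MetricsRecord(
        repeat_index=repeat_index,
        accuracy=float(accuracy),
        roc_auc=float(roc_auc_score(y_true, prob_positive)),
        f1=float(f1),
        tp=int(tp), fp=int(fp), tn=int(tn), fn=int(fn),
    )


@dataclass
class ExperimentResult:
    records: list[MetricsRecord]
    summary: pd.DataFrame
    importance_reports: list[ImportanceReport]
    mean_graph_importance: tuple[float, float, float]
    graph_stats_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    graphs_last: list[FeatureGraph] = field(default_factory=list)


def _summarise(records: list[MetricsRecord]) -> pd.DataFrame:
    rows = [
        {
            "repeat": rec.repeat_index,
            "accuracy": rec.accuracy,
            "roc_auc": rec.roc_auc,
            "f1": rec.f1,
            "tp": rec.tp, "fp": rec.fp, "tn": rec.tn, "fn": rec.fn,
        }
        for rec in records
    ]
    df = pd.DataFrame(rows)
    n = len(records)
    agg = {"repeat": "aggregate"}
    for metric in ("accuracy", "roc_auc", "f1"):
        vals = df[metric].to_numpy()
        mean = vals.mean()
        sd = vals.std(ddof=1) if n > 1 else 0.0
        half = 1.96 * sd / np.sqrt(n) if n > 1 else 0.0
        agg[metric] = mean
        agg[f"{metric}_sd"] = sd
        agg[f"{metric}_ci_low"] = mean - half
        agg[f"{metric}_ci_high"] = mean + half
    summary = pd.concat([df, pd.DataFrame([agg])], ignore_index=True)
    return summary


def run_experiment(
    X_list: list[OmicsMatrix] | None = None,
    y: LabelVector | None = None,
    synthetic: SyntheticConfig | None = None,
    model: str = "motgnn",
    train_cfg: TrainingConfig | None = None,
    scheme: SplitScheme | None = None,
    ensemble: EnsembleSpec | None = None,
    threshold: float = 0.5,
    normalize_on_train: bool = True,
    outdir: str | Path | None = None,
) -> ExperimentResult:
    """End-to-end repeated evaluation.

    ``model`` selects the graph generator: ``"motgnn"`` builds graphs from
    gradient-boosted trees, ``"motgnn_rf"`` from a random forest; the two
    variants are otherwise identical. With ``normalize_on_train`` (the
    default) min-max scaling is fitted on each repeat's training split and
    applied, clipped, to the whole dataset; disabling it scales the full
    dataset once up front.
    """
    if model not in ("motgnn", "motgnn_rf"):
        raise ValueError("model must be 'motgnn' or 'motgnn_rf'")
    if synthetic is not None:
        X_list, y, _ = generate_multiomics(synthetic)
    if X_list is None or y is None:
        raise ValueError("provide either data matrices + labels or a synthetic config")
    train_cfg = train_cfg or TrainingConfig()
    scheme = scheme or SplitScheme()
    ensemble = ensemble or EnsembleSpec()
    ensemble = replace(
        ensemble, method="random_forest" if model == "motgnn_rf" else "xgboost"
    )

    if not normalize_on_train:
        X_list = [minmax_normalize(X, X) for X in X_list]

    splits = stratified_splits(y, scheme)
    records: list[MetricsRecord] = []
    reports: list[ImportanceReport] = []
    graph_stat_rows: list[dict] = []
    graphs: list[FeatureGraph] = []
    for r, (train_idx, val_idx, test_idx) in enumerate(splits):
        try:
            if normalize_on_train:
                X_norm = [
                    minmax_normalize(X.subset_rows(train_idx), X) for X in X_list
                ]
            else:
                X_norm = X_list
            y_train = y.labels[train_idx]
            spec_r = replace(ensemble, seed=ensemble.seed + r)
            graphs = []
            for X in X_norm:
                recs = fit_tree_ensemble(X.subset_rows(train_idx), y_train, spec_r)
                graphs.append(build_feature_graph(recs, X.modality_id, X))
            cfg_r = replace(train_cfg, seed=train_cfg.seed + r)
            fitted, _ = train_motgnn(X_norm, y, graphs, cfg_r, train_idx, val_idx)
            prob = predict_positive_proba(fitted, graphs, X_norm, test_idx)
            records.append(
                compute_metrics(y.labels[test_idx], prob, threshold, repeat_index=r)
            )
            reports.append(build_report(fitted.encoders, graphs, fitted.fusion))
            for g in graphs:
                p_star, n_edges, ratio = graph_stats(g)
                graph_stat_rows.append(
                    {
                        "repeat": r,
                        "modality": g.modality_id,
                        "p_star": p_star,
                        "n_edges": n_edges,
                        "edge_node_ratio": ratio,
                    }
                )
        except Exception as exc:  # annotate with repeat context
            raise RuntimeError(f"repeat {r} failed: {exc}") from exc

    summary = _summarise(records)
    stats_table = pd.DataFrame(graph_stat_rows)
    rig_mean = tuple(
        float(v)
        for v in np.mean([rep.graph_importance for rep in reports], axis=0)
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        summary.to_csv(outdir / "metrics.tsv", sep="\t", index=False)
        stats_table.to_csv(outdir / "graph_stats.tsv", sep="\t", index=False)
        write_feature_importance(reports[-1], outdir / "feature_importance.tsv")
        write_graph_importance(reports[-1], outdir / "graph_importance.tsv")
        rig_df = pd.DataFrame([{f"RIG_{i + 1}": v for i, v in enumerate(rig_mean)}])
        rig_df.to_csv(outdir / "graph_importance_mean.tsv", sep="\t", index=False)
        write_graph_stats(graphs, outdir / "graph_stats_last_repeat.tsv")
        log = {
            "model": model,
            "threshold": threshold,
            "normalize_on_train": normalize_on_train,
            "training": vars(train_cfg),
            "ensemble": {
                "method": ensemble.method,
                "n_trees": ensemble.n_trees,
                "seed": ensemble.seed,
                "extra": ensemble.extra,
            },
            "splits": {
                "fractions": list(scheme.fractions),
                "n_repeats": scheme.n_repeats,
                "base_seed": scheme.base_seed,
            },
        }
        (outdir / "run_log.yaml").write_text(yaml.safe_dump(log, sort_keys=True))

    return ExperimentResult(
        records=records,
        summary=summary,
        importance_reports=reports,
        mean_graph_importance=rig_mean,  # type: ignore[arg-type]
        graph_stats_table=stats_table,
        graphs_last=graphs,
    )
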