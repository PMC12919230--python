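"""Connection-weights interpretability at feature and omics level.

Feature importance IF_j sums the absolute masked input-layer weights on
feature j's row, so only graph-supported connections contribute. Relative
graph importance RIG_i is the L1 norm of the fusion weights attached to
modality i's embedding, normalised across modalities to sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .nn import FusionClassifier, ModalityEncoder
from .tree_graph import FeatureGraph


@dataclass
class ImportanceReport:
    """Per-feature IF scores per modality, cross-modality combined scores,
    and the relative graph importances (one per modality, summing to 1)."""

    per_modality_feature_scores: dict[int, dict[str, float]]
    combined_scores: dict[str, float]
    graph_importance: tuple[float, float, float]


def feature_importance(enc: ModalityEncoder, g: FeatureGraph) -> dict[str, float]:
    """IF_j = sum_u |W_in[j, u]| over the positions where A~[j, u] = 1."""
    if enc.W_in.shape != (g.n_nodes, g.n_nodes):
        raise ValueError("encoder weight shape does not match the graph")
    scores = np.abs(enc.W_in * g.adjacency).sum(axis=1)
    return {name: float(s) for name, s in zip(g.nodes, scores)}


def aggregate_importance(
    per_modality: dict[int, dict[str, float]]
) -> dict[str, float]:
    """Sum scores of identically named features across modalities.

    Omics name spaces are usually disjoint, in which case this is simply the
    concatenation of the per-modality scores. The result is ordered by
    score descending, ties broken by name ascending.
    """
    combined: dict[str, float] = {}
    for scores in per_modality.values():
        for name, s in scores.items():
            combined[name] = combined.get(name, 0.0) + s
    return dict(sorted(combined.items(), key=lambda kv: (-kv[1], kv[0])))


def graph_importance(clf: FusionClassifier) -> tuple[float, ...]:
    """RIG_i = ||W_{Zi<->f}||_1 / sum_k ||W_{Zk<->f}||_1."""
    norms = np.array([np.abs(block).sum() for block in clf.fusion_blocks()])
    total = norms.sum()
    if total == 0:
        raise ValueError("degenerate fusion: all fusion weights are zero")
    return tuple(float(v) for v in norms / total)


def build_report(
    encoders: list[ModalityEncoder],
    graphs: list[FeatureGraph],
    clf: FusionClassifier,
) -> ImportanceReport:
    per_modality = {
        g.modality_id: feature_importance(enc, g)
        for enc, g in zip(encoders, graphs)
    }
    rig = graph_importance(clf)
    return ImportanceReport(
        per_modality_feature_scores=per_modality,
        combined_scores=aggregate_importance(per_modality),
        graph_importance=rig,  # type: ignore[arg-type]
    )


def top_k_biomarkers(report: ImportanceReport, k: int) -> list[str]:
    """The k features with the highest combined IF, score descending and
    ties broken by name ascending."""
    if k < 1:
        raise ValueError("k must be a positive integer")
    names = list(report.combined_scores)
    if k > len(names):
        raise ValueError(f"k={k} exceeds the {len(names)} scored features")
    return names[:k]


def write_feature_importance(report: ImportanceReport, path: str | Path) -> None:
    rows = []
    for modality, scores in sorted(report.per_modality_feature_scores.items()):
        ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        for rank, (name, score) in enumerate(ordered, start=1):
            rows.append({"modality": modality, "feature": name, "IF": score, "rank": rank})
    pd.DataFrame(rows, columns=["modality", "feature", "IF", "rank"]).to_csv(
        path, sep="\t", index=False
    )


def write_graph_importance(report: ImportanceReport, path: str | Path) -> None:
    rig = report.graph_importance
    pd.DataFrame([{f"RIG_{i + 1}": v for i, v in enumerate(rig)}]).to_csv(
        path, sep="\t", index=False
    )


def format_top_k(report: ImportanceReport, k: int) -> str:
    """Grouped plain-text report of the top-k features per modality."""
    lines = []
    for modality, scores in sorted(report.per_modality_feature_scores.items()):
        ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
        lines.append(f"modality {modality}")
        for rank, (name, score) in enumerate(ordered, start=1):
            lines.append(f"  {rank:3d}. {name}\t{score:.6f}")
    return "\n".join(lines) + "\n"
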