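"""Supervised feature graphs from tree ensembles.

A gradient-boosted (or random-forest) classifier is trained per modality;
the features its trees split on become graph nodes, and every direct
parent-child pair of split features becomes an undirected edge. The union
over all trees, plus a self-loop on every selected feature, defines the
modality's feature graph. The augmented adjacency matrix of that graph
later masks the input weights of the modality encoder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import LabelVector, OmicsMatrix, check_aligned


@dataclass
class TreeNodeRecord:
    """One node of one decision tree in a fitted ensemble."""

    tree_index: int
    node_id: int
    kind: str  # "split" | "leaf"
    split_feature: str | None = None
    children: tuple[int, int] | None = None  # (left, right) node_ids

    def __post_init__(self) -> None:
        if self.kind not in ("split", "leaf"):
            raise ValueError("kind must be 'split' or 'leaf'")
        if self.kind == "split" and (self.split_feature is None or self.children is None):
            raise ValueError("split nodes need split_feature and children")
        if self.kind == "leaf" and self.split_feature is not None:
            raise ValueError("leaves have no split_feature")


@dataclass
class EnsembleSpec:
    """Which ensemble to fit and how. ``extra`` hyperparameters are passed
    verbatim to the underlying library and recorded in run logs."""

    method: str = "xgboost"  # "xgboost" | "random_forest"
    n_trees: int = 100
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.method not in ("xgboost", "random_forest"):
            raise ValueError("method must be 'xgboost' or 'random_forest'")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class FeatureGraph:
    """Undirected feature graph of one modality, self-loops included.

    ``adjacency`` is the augmented binary matrix (symmetric, unit diagonal)
    over ``nodes``; ``col_map`` gives each node's column index in the
    original omics matrix; ``edges`` holds each unordered pair once, with
    self-pairs counted as edges.
    """

    modality_id: int
    nodes: list[str]
    edges: set[tuple[str, str]]
    adjacency: np.ndarray
    col_map: list[int]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def _parse_xgboost(model) -> list[TreeNodeRecord]:
    df = model.get_booster().trees_to_dataframe()
    records: list[TreeNodeRecord] = []
    for _, row in df.sort_values(["Tree", "Node"]).iterrows():
        tree = int(row["Tree"])
        node = int(row["Node"])
        if row["Feature"] == "Leaf":
            records.append(TreeNodeRecord(tree, node, "leaf"))
        else:
            left = int(str(row["Yes"]).split("-")[1])
            right = int(str(row["No"]).split("-")[1])
            records.append(
                TreeNodeRecord(tree, node, "split", str(row["Feature"]), (left, right))
            )
    return records


def _parse_random_forest(model, feature_names: list[str]) -> list[TreeNodeRecord]:
    records: list[TreeNodeRecord] = []
    for t, est in enumerate(model.estimators_):
        tree = est.tree_
        for node in range(tree.node_count):
            f = tree.feature[node]
            if f < 0:
                records.append(TreeNodeRecord(t, node, "leaf"))
            else:
                records.append(
                    TreeNodeRecord(
                        t,
                        node,
                        "split",
                        feature_names[f],
                        (int(tree.children_left[node]), int(tree.children_right[node])),
                    )
                )
    return records


def fit_tree_ensemble(
    X: OmicsMatrix, y: LabelVector | np.ndarray, spec: EnsembleSpec
) -> list[TreeNodeRecord]:
    """Fit one supervised tree ensemble and return its parsed node records.

    Single-threaded and seeded, so the records are reproducible bit-for-bit
    for the same inputs.
    """
    spec.validate()
    if isinstance(y, LabelVector):
        check_aligned(X, y)
        labels = y.labels
    else:
        labels = np.asarray(y, dtype=int)
        if labels.shape[0] != X.n_samples:
            raise ValueError("label length does not match matrix rows")
    if len(np.unique(labels)) < 2:
        raise ValueError("cannot fit an ensemble on single-class labels")

    frame = X.to_frame()
    if spec.method == "xgboost":
        from xgboost import XGBClassifier

        model = XGBClassifier(
            n_estimators=spec.n_trees,
            random_state=spec.seed,
            n_jobs=1,
            **spec.extra,
        )
        model.fit(frame, labels)
        return _parse_xgboost(model)

    from sklearn.ensemble import RandomForestClassifier

    model = RandomForestClassifier(
        n_estimators=spec.n_trees,
        random_state=spec.seed,
        n_jobs=1,
        **spec.extra,
    )
    model.fit(frame.to_numpy(), labels)
    return _parse_random_forest(model, X.feature_names)


def selected_features(records: list[TreeNodeRecord]) -> list[str]:
    """Distinct split features across all trees, in first-appearance order
    (records iterated in (tree_index, node_id) order)."""
    ordered = sorted(records, key=lambda r: (r.tree_index, r.node_id))
    seen: dict[str, None] = {}
    for rec in ordered:
        if rec.kind == "split" and rec.split_feature not in seen:
            seen[rec.split_feature] = None
    return list(seen)


def _pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def build_feature_graph(
    records: list[TreeNodeRecord],
    modality_id: int,
    X: OmicsMatrix,
    path_closure: bool = False,
) -> FeatureGraph:
    """Union of parent-child split-feature pairs over all trees, plus
    self-loops on every selected feature.

    An edge is added between the split features of a split node and each of
    its split-node children; edges into leaves contribute nothing. With
    ``path_closure=True`` every pair of split features on a common
    root-to-leaf path is connected instead (a denser, transitive reading).
    """
    nodes = selected_features(records)
    if not nodes:
        raise ValueError("empty graph: no feature was used in any split")
    known = set(X.feature_names)
    unknown = [f for f in nodes if f not in known]
    if unknown:
        raise ValueError(f"split features not present in matrix: {unknown[:5]}")

    by_tree: dict[int, dict[int, TreeNodeRecord]] = {}
    for rec in records:
        by_tree.setdefault(rec.tree_index, {})[rec.node_id] = rec

    edges: set[tuple[str, str]] = {(f, f) for f in nodes}
    for tree in by_tree.values():
        splits = {nid: r for nid, r in tree.items() if r.kind == "split"}
        if path_closure:
            roots = set(tree) - {
                c for r in splits.values() for c in r.children
            }
            for root in roots:
                _closure_edges(tree, root, [], edges)
        else:
            for rec in splits.values():
                for child_id in rec.children:
                    child = tree.get(child_id)
                    if child is None:
                        raise ValueError(
                            f"child node {child_id} missing in tree {rec.tree_index}"
                        )
                    if child.kind == "split":
                        edges.add(_pair(rec.split_feature, child.split_feature))

    index = {f: i for i, f in enumerate(nodes)}
    adjacency = np.zeros((len(nodes), len(nodes)), dtype=int)
    for a, b in edges:
        adjacency[index[a], index[b]] = 1
        adjacency[index[b], index[a]] = 1
    col_index = {f: i for i, f in enumerate(X.feature_names)}
    return FeatureGraph(
        modality_id=modality_id,
        nodes=nodes,
        edges=edges,
        adjacency=adjacency,
        col_map=[col_index[f] for f in nodes],
    )


def _closure_edges(tree, node_id, ancestors, edges) -> None:
    rec = tree[node_id]
    if rec.kind != "split":
        return
    for anc in ancestors:
        edges.add(_pair(anc, rec.split_feature))
    for child_id in rec.children:
        _closure_edges(tree, child_id, ancestors + [rec.split_feature], edges)


def graph_stats(g: FeatureGraph) -> tuple[int, int, float]:
    """(p*, |E|, m) — node count, edge count including self-loops, and the
    edge-to-node ratio m = |E| / p*."""
    return g.n_nodes, g.n_edges, g.n_edges / g.n_nodes


def to_networkx(g: FeatureGraph) -> nx.Graph:
    graph = nx.Graph()
    graph.add_nodes_from(g.nodes)
    graph.add_edges_from(g.edges)
    return graph


def write_edge_list(g: FeatureGraph, path: str | Path) -> None:
    rows = [
        {"feature_a": a, "feature_b": b, "is_self_loop": int(a == b)}
        for a, b in sorted(g.edges)
    ]
    pd.DataFrame(rows, columns=["feature_a", "feature_b", "is_self_loop"]).to_csv(
        path, sep="\t", index=False
    )


def write_graphml(g: FeatureGraph, path: str | Path) -> None:
    nx.write_graphml(to_networkx(g), str(path))


def write_graph_stats(graphs: list[FeatureGraph], path: str | Path) -> None:
    """One row per modality: node count p*, edge count |E| (self-loops
    included) and edge-to-node ratio m."""
    rows = []
    for g in graphs:
        p_star, n_edges, ratio = graph_stats(g)
        rows.append(
            {
                "modality": g.modality_id,
                "p_star": p_star,
                "n_edges": n_edges,
                "edge_node_ratio": ratio,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
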