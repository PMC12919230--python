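"""Independent brute-force oracle for feature-graph construction, plus a
random toy-ensemble generator. Kept deliberately separate from the package:
the oracle enumerates parent-child split pairs directly from the node
records without any of the package's graph machinery."""

from __future__ import annotations

import numpy as np

from motgnn import TreeNodeRecord


def bruteforce_edges(records: list[TreeNodeRecord]) -> set[tuple[str, str]]:
    """Every unordered pair of split features joined by a direct
    parent-child link in any tree, plus a self-pair per split feature."""
    edges: set[tuple[str, str]] = set()
    features: set[str] = set()
    by_tree: dict[int, dict[int, TreeNodeRecord]] = {}
    for rec in records:
        by_tree.setdefault(rec.tree_index, {})[rec.node_id] = rec
    for tree in by_tree.values():
        for rec in tree.values():
            if rec.kind != "split":
                continue
            features.add(rec.split_feature)
            for child_id in rec.children:
                child = tree[child_id]
                if child.kind == "split":
                    a, b = sorted((rec.split_feature, child.split_feature))
                    edges.add((a, b))
    edges.update((f, f) for f in features)
    return edges


def random_toy_ensemble(
    rng: np.random.Generator,
    n_trees: int = 3,
    max_splits: int = 7,
    n_features: int = 6,
) -> list[TreeNodeRecord]:
    """A random ensemble of small binary trees. Each tree grows top-down:
    a frontier node either becomes a split (two new children) or a leaf."""
    feature_pool = [f"f{j}" for j in range(n_features)]
    records: list[TreeNodeRecord] = []
    for t in range(rng.integers(1, n_trees + 1)):
        n_splits = int(rng.integers(0, max_splits + 1))
        next_id = 1
        frontier = [0]
        splits_done = 0
        while frontier:
            node = frontier.pop(0)
            remaining_slots = len(frontier)
            can_split = splits_done < n_splits
            # bias toward splitting while budget remains
            if can_split and (remaining_slots == 0 or rng.random() < 0.7):
                left, right = next_id, next_id + 1
                next_id += 2
                records.append(
                    TreeNodeRecord(
                        t, node, "split",
                        str(rng.choice(feature_pool)), (left, right),
                    )
                )
                frontier.extend([left, right])
                splits_done += 1
            else:
                records.append(TreeNodeRecord(t, node, "leaf"))
    return records
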