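"""Delimited-text readers and writers for omics matrices, labels and graphs.

Matrices are TSV/CSV with the sample ID in the first column and feature
names in the header row. Labels are two-column TSV (sample_id, label).
The delimiter is inferred from the file suffix (.csv -> comma, else tab).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .datatypes import LabelVector, OmicsMatrix


def _sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_matrix(path: str | Path, modality_id: int) -> OmicsMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    return OmicsMatrix.from_frame(df, modality_id=modality_id)


def write_matrix(matrix: OmicsMatrix, path: str | Path) -> None:
    path = Path(path)
    matrix.to_frame().to_csv(path, sep=_sep(path), index_label="sample_id")


def read_labels(path: str | Path) -> LabelVector:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path))
    if df.shape[1] != 2:
        raise ValueError("label file must have exactly two columns (sample_id, label)")
    return LabelVector(
        labels=df.iloc[:, 1].to_numpy(dtype=int),
        sample_ids=[str(s) for s in df.iloc[:, 0]],
    )


def write_labels(labels: LabelVector, path: str | Path) -> None:
    path = Path(path)
    ids = labels.sample_ids or [str(i) for i in range(labels.n_samples)]
    pd.DataFrame({"sample_id": ids, "label": labels.labels}).to_csv(
        path, sep=_sep(path), index=False
    )


def read_feature_list(path: str | Path) -> list[str]:
    text = Path(path).read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]


def write_feature_list(names: list[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{n}\n" for n in names))


def load_config(path: str | Path) -> dict:
    """Load a flat key-value YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a flat key-value mapping")
    return cfg
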