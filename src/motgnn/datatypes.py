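"""Core in-memory containers for multi-omics classification.

An analysis operates on up to three modalities (DNA methylation, mRNA
expression, miRNA expression) measured on the same ordered set of samples,
plus a binary label per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def _check_unique(names: list[str], what: str) -> None:
    if len(set(names)) != len(names):
        raise ValueError(f"{what} must be unique")


@dataclass
class OmicsMatrix:
    """One modality's samples x features table.

    Parameters
    ----------
    values : (n_samples, n_features) float array, no missing values.
    sample_ids : ordered unique sample identifiers (rows).
    feature_names : ordered unique feature identifiers (columns).
    modality_id : which omics layer this is (1, 2 or 3).
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_names: list[str]
    modality_id: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = list(self.sample_ids)
        self.feature_names = list(self.feature_names)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-dimensional")
        n, p = self.values.shape
        if n != len(self.sample_ids):
            raise ValueError(
                f"row count {n} != number of sample_ids {len(self.sample_ids)}"
            )
        if p != len(self.feature_names):
            raise ValueError(
                f"column count {p} != number of feature_names {len(self.feature_names)}"
            )
        _check_unique(self.sample_ids, "sample_ids")
        _check_unique(self.feature_names, "feature_names")
        if self.modality_id not in (1, 2, 3):
            raise ValueError("modality_id must be 1, 2 or 3")
        if not np.isfinite(self.values).all():
            raise ValueError("values contain non-finite entries")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_rows(self, idx: np.ndarray) -> "OmicsMatrix":
        """Return a new matrix restricted to the given row positions."""
        idx = np.asarray(idx, dtype=int)
        return OmicsMatrix(
            values=self.values[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            feature_names=self.feature_names,
            modality_id=self.modality_id,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.feature_names
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, modality_id: int) -> "OmicsMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            sample_ids=[str(s) for s in df.index],
            feature_names=[str(c) for c in df.columns],
            modality_id=modality_id,
        )


@dataclass
class LabelVector:
    """Binary labels (0/1) aligned to an ordered sample-ID list."""

    labels: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be 1-dimensional")
        if not np.isin(self.labels, [0, 1]).all():
            raise ValueError("labels must be 0 or 1")
        if self.sample_ids:
            if len(self.sample_ids) != self.labels.shape[0]:
                raise ValueError("sample_ids length != number of labels")
            _check_unique(self.sample_ids, "sample_ids")
        if len(np.unique(self.labels)) < 2:
            raise ValueError("both classes must be present in labels")

    @property
    def n_samples(self) -> int:
        return self.labels.shape[0]

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    def subset(self, idx: np.ndarray) -> np.ndarray:
        """Label values at the given row positions (plain array; a subset
        may legally be single-class)."""
        return self.labels[np.asarray(idx, dtype=int)]


def check_aligned(X: OmicsMatrix, y: LabelVector) -> None:
    """Raise if a matrix and a label vector do not describe the same samples."""
    if X.n_samples != y.n_samples:
        raise ValueError(
            f"matrix has {X.n_samples} samples but labels have {y.n_samples}"
        )
    if y.sample_ids and y.sample_ids != X.sample_ids:
        raise ValueError("sample_ids of matrix and labels differ")
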