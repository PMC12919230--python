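"""Synthetic multi-omics data with planted class signal.

Generates three heterogeneous modalities whose marginal distributions mimic
the shapes seen in real tumour profiling data after [0,1] scaling:

* ``bimodal`` — methylation-like beta mixture with mass near 0 and near 1;
* ``right_skewed`` — expression-like exponential tail;
* ``sparse`` — miRNA-like point mass at zero plus a positive tail.

A configurable subset of features per modality is informative: their
class-conditional means differ by ``effect_size`` (on the pre-scaling
scale) before Gaussian noise is added. All other features are independent
of the label. Every matrix is min-max scaled per feature to [0,1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import LabelVector, OmicsMatrix

_STYLES = ("bimodal", "right_skewed", "sparse")
_MODALITY_PREFIX = {1: "meth", 2: "mrna", 3: "mirna"}


@dataclass
class SyntheticConfig:
    """Recipe for one synthetic multi-omics dataset.

    ``class_ratio`` is the positive-class fraction; the number of positives
    is ``round(n_samples * class_ratio)`` with ties rounded half up, so
    stratum sizes are exactly reproducible. ``effect_size`` is the between-
    class mean shift applied to informative features before per-feature
    min-max scaling; ``noise_sd`` is the SD of additive Gaussian noise on
    every entry.
    """

    n_samples: int = 300
    class_ratio: float = 0.5
    dims: tuple[int, int, int] = (100, 100, 40)
    informative_per_modality: tuple[int, int, int] = (10, 10, 5)
    effect_size: float = 1.0
    noise_sd: float = 0.5
    modality_styles: tuple[str, str, str] = ("bimodal", "right_skewed", "sparse")
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be at least 2")
        if not 0.0 < self.class_ratio < 1.0:
            raise ValueError("class_ratio must lie strictly in (0, 1)")
        if len(self.dims) != 3 or any(d < 1 for d in self.dims):
            raise ValueError("dims must be three positive feature counts")
        if len(self.informative_per_modality) != 3:
            raise ValueError("informative_per_modality must have three entries")
        for i, (k, p) in enumerate(zip(self.informative_per_modality, self.dims)):
            if k < 0 or k > p:
                raise ValueError(
                    f"informative_per_modality[{i}]={k} must be in [0, dims[{i}]={p}]"
                )
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if len(self.modality_styles) != 3 or any(
            s not in _STYLES for s in self.modality_styles
        ):
            raise ValueError(f"modality_styles entries must be one of {_STYLES}")
        minority = min(self.class_ratio, 1.0 - self.class_ratio)
        if self.n_samples * minority < 5:
            raise ValueError(
                "n_samples * min(class_ratio, 1-class_ratio) must be >= 5 "
                "so every split stratum is non-empty"
            )


def _n_positive(n: int, ratio: float) -> int:
    # round half up for reproducible stratum sizes
    return int(np.floor(n * ratio + 0.5))


def _base_matrix(style: str, n: int, p: int, rng: np.random.Generator) -> np.ndarray:
    if style == "bimodal":
        mode = rng.random((n, p)) < 0.5
        low = rng.beta(2.0, 10.0, size=(n, p))
        high = rng.beta(10.0, 2.0, size=(n, p))
        return np.where(mode, high, low)
    if style == "right_skewed":
        return rng.exponential(scale=0.3, size=(n, p))
    if style == "sparse":
        zero = rng.random((n, p)) < 0.5
        tail = rng.exponential(scale=0.4, size=(n, p))
        return np.where(zero, 0.0, tail)
    raise ValueError(f"unknown modality style {style!r}")


def _scale_unit(values: np.ndarray) -> np.ndarray:
    lo = values.min(axis=0)
    span = values.max(axis=0) - lo
    span[span == 0.0] = 1.0
    return (values - lo) / span


def generate_multiomics(
    config: SyntheticConfig,
) -> tuple[list[OmicsMatrix], LabelVector, dict[int, list[str]]]:
    """Generate three omics matrices, labels, and the planted-feature truth.

    Returns
    -------
    matrices : list of three :class:`OmicsMatrix` (modality_id 1, 2, 3)
    labels : :class:`LabelVector` with exactly round(n * class_ratio) positives
    informative : modality_id -> names of the planted informative features

    Deterministic for a fixed ``config.seed``; the same seed with a larger
    ``effect_size`` reuses identical base and noise draws so only the planted
    shift changes.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    label_rng, *mod_rngs = [np.random.default_rng(s) for s in ss.spawn(4)]

    n = config.n_samples
    n_pos = _n_positive(n, config.class_ratio)
    labels = np.zeros(n, dtype=int)
    labels[label_rng.permutation(n)[:n_pos]] = 1
    sample_ids = [f"S{i:04d}" for i in range(n)]

    matrices: list[OmicsMatrix] = []
    informative: dict[int, list[str]] = {}
    for mi, (p, k, style, rng) in enumerate(
        zip(config.dims, config.informative_per_modality, config.modality_styles, mod_rngs),
        start=1,
    ):
        prefix = _MODALITY_PREFIX[mi]
        names = [f"{prefix}_{j:04d}" for j in range(p)]
        base = _base_matrix(style, n, p, rng)
        noise = rng.normal(0.0, 1.0, size=(n, p)) * config.noise_sd
        # planted features are spread through the matrix, not bunched at the
        # front, so column position carries no information
        planted = rng.permutation(p)[:k]
        values = base + noise
        values[:, planted] += config.effect_size * labels[:, None]
        matrices.append(
            OmicsMatrix(
                values=_scale_unit(values),
                sample_ids=sample_ids,
                feature_names=names,
                modality_id=mi,
            )
        )
        informative[mi] = sorted(names[j] for j in planted)

    return matrices, LabelVector(labels=labels, sample_ids=sample_ids), informative


def minmax_normalize(train: OmicsMatrix, apply_to: OmicsMatrix) -> OmicsMatrix:
    """Per-feature min-max scaling fitted on ``train``, applied to ``apply_to``.

    Each feature is mapped through (x - min_train) / (max_train - min_train)
    and clipped to [0, 1]; features constant in the training data map to 0.
    """
    if train.feature_names != apply_to.feature_names:
        raise ValueError("feature names of apply_to do not match the training matrix")
    lo = train.values.min(axis=0)
    span = train.values.max(axis=0) - lo
    constant = span == 0.0
    span = np.where(constant, 1.0, span)
    scaled = (apply_to.values - lo) / span
    scaled[:, constant] = 0.0
    np.clip(scaled, 0.0, 1.0, out=scaled)
    return OmicsMatrix(
        values=scaled,
        sample_ids=apply_to.sample_ids,
        feature_names=apply_to.feature_names,
        modality_id=apply_to.modality_id,
    )
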