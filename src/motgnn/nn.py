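"""Graph-embedded encoders, cross-omics fusion classifier, and training.

Each modality gets an encoder whose first layer is a dense layer of width
p* (the number of selected features) whose weight matrix is multiplied
element-wise by the augmented adjacency matrix A~ of the modality's feature
graph at every forward pass:

    Z1 = ReLU(X* (W_in ⊙ A~) + b_in)

so only graph-supported connections can ever influence the output. The
encoder embeddings are concatenated and passed through a feedforward
fusion network ending in a 2-unit softmax head. Training minimises binary
cross-entropy on the positive-class probability plus an L2 penalty
lambda * sum(w^2), with mini-batch Adam, dropout, batch normalisation and
early stopping on validation loss.

The implementation is plain NumPy: the networks involved have at most a
few hundred units per layer, and a from-scratch implementation keeps
training single-threaded and bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

from .datatypes import LabelVector, OmicsMatrix
from .tree_graph import FeatureGraph

_EPS_PROB = 1e-7


# ---------------------------------------------------------------------------
# parameters and layers


class Param:
    """A trainable array with its gradient, Adam state and L2 treatment.

    ``decay_mask`` is ``None`` for parameters exempt from weight decay
    (biases, batch-norm scales), ``1.0`` for dense weights, or a binary
    array restricting decay to the effective (unmasked) entries.
    """

    __slots__ = ("value", "grad", "m", "v", "decay_mask")

    def __init__(self, value: np.ndarray, decay_mask=None):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)
        self.decay_mask = decay_mask


class Dense:
    def __init__(self, w: np.ndarray, b: np.ndarray):
        self.w = Param(w, decay_mask=1.0)
        self.b = Param(b)
        self._x = None

    def params(self):
        return [self.w, self.b]

    def effective_weight(self) -> np.ndarray:
        return self.w.value

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.effective_weight() + self.b.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ g
        self.b.grad += g.sum(axis=0)
        return g @ self.effective_weight().T


class MaskedDense(Dense):
    """Dense layer whose weights are Hadamard-masked by a fixed binary
    adjacency at every forward pass; masked positions stay inert under
    optimisation because their gradients are masked too."""

    def __init__(self, w: np.ndarray, b: np.ndarray, mask: np.ndarray):
        super().__init__(w, b)
        self.mask = np.asarray(mask, dtype=float)
        if self.mask.shape != self.w.value.shape:
            raise ValueError("mask shape does not match weight shape")
        self.w.decay_mask = self.mask

    def effective_weight(self) -> np.ndarray:
        return self.w.value * self.mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.w.grad += (self._x.T @ g) * self.mask
        self.b.grad += g.sum(axis=0)
        return g @ self.effective_weight().T


class ReLU:
    def __init__(self):
        self._keep = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._keep = x > 0
        return np.where(self._keep, x, 0.0)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._keep


class Dropout:
    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g if self._mask is None else g * self._mask


class BatchNorm:
    """Standard batch normalisation with running statistics for inference."""

    def __init__(self, dim: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(dim))
        self.beta = Param(np.zeros(dim))
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            inv_std = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mu) * inv_std
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            self._cache = (xhat, inv_std)
            return self.gamma.value * xhat + self.beta.value
        xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        n = g.shape[0]
        self.gamma.grad += (g * xhat).sum(axis=0)
        self.beta.grad += g.sum(axis=0)
        dxhat = g * self.gamma.value
        return (inv_std / n) * (
            n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
        )


# ---------------------------------------------------------------------------
# model


@dataclass
class TrainingConfig:
    """Optimisation settings; defaults follow the tuned grid values
    (lr 1e-4, batch 16, 500 epochs, dropout 0.5, lambda 0.01, patience 10,
    min_delta 1e-3)."""

    learning_rate: float = 1e-4
    batch_size: int = 16
    epochs: int = 500
    dropout: float = 0.5
    l2_lambda: float = 0.01
    patience: int = 10
    min_delta: float = 0.001
    depth: int = 1
    width: int = 64
    seed: int = 0

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.l2_lambda < 0:
            raise ValueError("l2_lambda must be non-negative")
        if self.patience < 1 or self.min_delta < 0:
            raise ValueError("patience must be >= 1 and min_delta >= 0")
        if self.depth < 0 or self.width < 1:
            raise ValueError("depth must be >= 0 and width >= 1")


class ModalityEncoder:
    """Graph-embedded layer followed by ``depth`` dense blocks
    (affine -> batch norm -> ReLU -> dropout) of ``width`` units."""

    def __init__(
        self,
        adjacency: np.ndarray,
        depth: int,
        width: int,
        dropout: float,
        init_rng: np.random.Generator,
        dropout_rng: np.random.Generator,
    ):
        adjacency = np.asarray(adjacency)
        p = adjacency.shape[0]
        if adjacency.shape != (p, p):
            raise ValueError("adjacency must be square")
        self.adjacency = adjacency.astype(float)
        w0 = init_rng.normal(0.0, np.sqrt(2.0 / p), size=(p, p))
        # inputs are [0,1]-scaled and the mask can leave a unit with a
        # single (possibly negative) incoming weight; a small positive bias
        # keeps every ReLU unit trainable at initialisation
        self.input_layer = MaskedDense(w0, np.full(p, 0.1), self.adjacency)
        self.input_act = ReLU()
        self.input_drop = Dropout(dropout, dropout_rng)
        self.blocks: list[list] = []
        fan_in = p
        for _ in range(depth):
            w = init_rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, width))
            self.blocks.append(
                [Dense(w, np.zeros(width)), BatchNorm(width), ReLU(), Dropout(dropout, dropout_rng)]
            )
            fan_in = width
        self.embedding_width = fan_in

    @property
    def W_in(self) -> np.ndarray:
        return self.input_layer.w.value

    @W_in.setter
    def W_in(self, value: np.ndarray) -> None:
        self.input_layer.w.value = np.asarray(value, dtype=float)

    @property
    def b_in(self) -> np.ndarray:
        return self.input_layer.b.value

    def _layers(self):
        yield self.input_layer
        yield self.input_act
        yield self.input_drop
        for block in self.blocks:
            yield from block

    def params(self):
        return [p for layer in self._layers() for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self._layers():
            x = layer.forward(x, train)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(list(self._layers())):
            g = layer.backward(g)
        return g


class FusionClassifier:
    """Fusion of the modality embeddings: one hidden dense block over the
    concatenated embedding, then a 2-unit softmax head. The slices of the
    first weight matrix belonging to each modality block are exposed for
    graph-importance scoring."""

    def __init__(
        self,
        block_widths: list[int],
        width: int,
        dropout: float,
        init_rng: np.random.Generator,
        dropout_rng: np.random.Generator,
    ):
        self.block_widths = list(block_widths)
        total = sum(block_widths)
        w = init_rng.normal(0.0, np.sqrt(2.0 / total), size=(total, width))
        self.fuse = Dense(w, np.zeros(width))
        self.bn = BatchNorm(width)
        self.act = ReLU()
        self.drop = Dropout(dropout, dropout_rng)
        self.head = Dense(
            init_rng.normal(0.0, np.sqrt(2.0 / width), size=(width, 2)), np.zeros(2)
        )

    def fusion_blocks(self) -> list[np.ndarray]:
        """W_{Zi<->f}: the rows of the first fusion weight matrix fed by
        each modality's embedding, in modality order."""
        out, start = [], 0
        for width in self.block_widths:
            out.append(self.fuse.w.value[start : start + width, :])
            start += width
        return out

    def _layers(self):
        return [self.fuse, self.bn, self.act, self.drop, self.head]

    def params(self):
        return [p for layer in self._layers() for p in layer.params()]

    def forward(self, z: np.ndarray, train: bool) -> np.ndarray:
        for layer in self._layers():
            z = layer.forward(z, train)
        return z  # logits

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self._layers()):
            g = layer.backward(g)
        return g


def softmax(logits: np.ndarray) -> np.ndarray:
    logp = logits - logsumexp(logits, axis=1, keepdims=True)
    return np.exp(logp)


class MOTGNNModel:
    """Three modality encoders plus the fusion classifier."""

    def __init__(self, encoders: list[ModalityEncoder], fusion: FusionClassifier):
        self.encoders = encoders
        self.fusion = fusion

    def params(self):
        out = [p for enc in self.encoders for p in enc.params()]
        out.extend(self.fusion.params())
        return out

    def forward(self, xstars: list[np.ndarray], train: bool) -> np.ndarray:
        zs = [enc.forward(x, train) for enc, x in zip(self.encoders, xstars)]
        self._z_widths = [z.shape[1] for z in zs]
        return self.fusion.forward(np.concatenate(zs, axis=1), train)

    def backward(self, dlogits: np.ndarray) -> None:
        dz = self.fusion.backward(dlogits)
        start = 0
        for enc, width in zip(self.encoders, self._z_widths):
            enc.backward(dz[:, start : start + width])
            start += width

    def predict_proba(self, xstars: list[np.ndarray]) -> np.ndarray:
        return softmax(self.forward(xstars, train=False))

    def calibrate_batchnorm(self, xstars: list[np.ndarray]) -> None:
        """Set every batch-norm layer's inference statistics to the exact
        moments of its input over the given (training) data, computed with
        dropout off.

        Running averages accumulated during training see dropout-perturbed
        activations, whose variance differs from inference-time activations;
        on small networks the mismatch distorts validation loss badly. A
        single full-batch recalibration pass removes it.
        """

        def through(layers, x):
            for layer in layers:
                if isinstance(layer, BatchNorm):
                    layer.running_mean = x.mean(axis=0)
                    layer.running_var = x.var(axis=0)
                x = layer.forward(x, train=False)
            return x

        zs = [through(enc._layers(), x) for enc, x in zip(self.encoders, xstars)]
        through(self.fusion._layers(), np.concatenate(zs, axis=1))

    # -- weight snapshots for early stopping ------------------------------
    def _state(self):
        arrays = [p.value.copy() for p in self.params()]
        buffers = []
        for enc in self.encoders:
            for block in enc.blocks:
                buffers.append((block[1].running_mean.copy(), block[1].running_var.copy()))
        buffers.append((self.fusion.bn.running_mean.copy(), self.fusion.bn.running_var.copy()))
        return arrays, buffers

    def _load_state(self, state) -> None:
        arrays, buffers = state
        for p, value in zip(self.params(), arrays):
            p.value = value.copy()
        it = iter(buffers)
        for enc in self.encoders:
            for block in enc.blocks:
                mean, var = next(it)
                block[1].running_mean = mean.copy()
                block[1].running_var = var.copy()
        mean, var = next(it)
        self.fusion.bn.running_mean = mean.copy()
        self.fusion.bn.running_var = var.copy()


def build_motgnn(graphs: list[FeatureGraph], cfg: TrainingConfig) -> MOTGNNModel:
    """Construct an untrained model whose encoder masks are the augmented
    adjacencies of the given feature graphs."""
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    init_rng, dropout_rng = [np.random.default_rng(s) for s in ss.spawn(2)]
    encoders = [
        ModalityEncoder(g.adjacency, cfg.depth, cfg.width, cfg.dropout, init_rng, dropout_rng)
        for g in graphs
    ]
    fusion = FusionClassifier(
        [enc.embedding_width for enc in encoders], cfg.width, cfg.dropout,
        init_rng, dropout_rng,
    )
    return MOTGNNModel(encoders, fusion)


# ---------------------------------------------------------------------------
# the spec'd functional operations


def graph_embedded_forward(
    xstar: np.ndarray, adjacency: np.ndarray, enc: ModalityEncoder
) -> np.ndarray:
    """The graph-embedded layer alone: ReLU(X* (W_in ⊙ A~) + b_in)."""
    xstar = np.asarray(xstar, dtype=float)
    adjacency = np.asarray(adjacency, dtype=float)
    p = adjacency.shape[0]
    if adjacency.shape != (p, p) or xstar.shape[1] != p or enc.W_in.shape != (p, p):
        raise ValueError("shape mismatch between input, adjacency and encoder")
    return np.maximum(0.0, xstar @ (enc.W_in * adjacency) + enc.b_in)


def encode_modality(
    xstar: np.ndarray, g: FeatureGraph, enc: ModalityEncoder, train_mode: bool = False
) -> np.ndarray:
    """Full encoder pass producing the modality embedding Z_i."""
    xstar = np.asarray(xstar, dtype=float)
    if xstar.shape[1] != g.n_nodes:
        raise ValueError(
            f"input has {xstar.shape[1]} columns but graph has {g.n_nodes} nodes; "
            "columns must follow g.col_map"
        )
    if enc.adjacency.shape[0] != g.n_nodes:
        raise ValueError("encoder was built for a different graph")
    return enc.forward(xstar, train_mode)


def fuse_and_classify(
    z1: np.ndarray, z2: np.ndarray, z3: np.ndarray,
    clf: FusionClassifier, train_mode: bool = False,
) -> np.ndarray:
    """Concatenate the modality embeddings in order 1,2,3 and return the
    per-sample softmax probability pair (rows sum to 1)."""
    if not (z1.shape[0] == z2.shape[0] == z3.shape[0]):
        raise ValueError("sample counts of the embeddings differ")
    logits = clf.forward(np.concatenate([z1, z2, z3], axis=1), train_mode)
    return softmax(logits)


def bce_loss(y: np.ndarray, p: np.ndarray) -> float:
    """Binary cross-entropy of positive-class probabilities, with
    probabilities clipped to [1e-7, 1 - 1e-7]."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape:
        raise ValueError("label and probability vectors have different lengths")
    p = np.clip(p, _EPS_PROB, 1.0 - _EPS_PROB)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


# ---------------------------------------------------------------------------
# optimisation


class Adam:
    def __init__(self, params: list[Param], lr: float, l2_lambda: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.l2 = l2_lambda
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p in self.params:
            g = p.grad
            if self.l2 > 0 and p.decay_mask is not None:
                g = g + 2.0 * self.l2 * p.value * p.decay_mask
            p.m = self.beta1 * p.m + (1 - self.beta1) * g
            p.v = self.beta2 * p.v + (1 - self.beta2) * g * g
            p.value = p.value - self.lr * (p.m / b1t) / (np.sqrt(p.v / b2t) + self.eps)
            p.grad = np.zeros_like(p.grad)


def _l2_penalty(model: MOTGNNModel, lam: float) -> float:
    if lam == 0:
        return 0.0
    total = 0.0
    for p in model.params():
        if p.decay_mask is not None:
            total += float(np.sum((p.value * p.decay_mask) ** 2))
    return lam * total


def _bce_from_logits(logits: np.ndarray, y: np.ndarray) -> float:
    logp = logits - logsumexp(logits, axis=1, keepdims=True)
    return float(-np.mean(logp[np.arange(len(y)), y]))


def train_motgnn(
    X_list: list[OmicsMatrix],
    y: LabelVector,
    graphs: list[FeatureGraph],
    cfg: TrainingConfig,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
) -> tuple[MOTGNNModel, list[dict]]:
    """Fit the full model with mini-batch Adam and early stopping.

    ``X_list`` are the (normalised) full matrices; rows are selected with
    ``train_idx`` / ``val_idx`` and columns reduced through each graph's
    ``col_map``. Validation loss is plain BCE; training stops once it has
    failed to improve by ``min_delta`` for ``patience`` consecutive epochs,
    and the best-validation weights are restored.
    """
    cfg.validate()
    train_idx = np.asarray(train_idx, dtype=int)
    val_idx = np.asarray(val_idx, dtype=int)
    for name, idx in (("training", train_idx), ("validation", val_idx)):
        strata = np.unique(y.labels[idx])
        if len(strata) < 2:
            raise ValueError(f"empty {name} stratum: both classes required")

    xstars = [X.values[:, g.col_map] for X, g in zip(X_list, graphs)]
    x_train = [x[train_idx] for x in xstars]
    x_val = [x[val_idx] for x in xstars]
    y_train = y.labels[train_idx]
    y_val = y.labels[val_idx]

    model = build_motgnn(graphs, cfg)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(3)[2])
    opt = Adam(model.params(), cfg.learning_rate, cfg.l2_lambda)

    n_train = len(train_idx)
    history: list[dict] = []
    best_val = np.inf
    best_state = model._state()
    stall = 0
    for epoch in range(1, cfg.epochs + 1):
        order = shuffle_rng.permutation(n_train)
        batch_losses = []
        for start in range(0, n_train, cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            xb = [x[batch] for x in x_train]
            yb = y_train[batch]
            logits = model.forward(xb, train=True)
            probs = softmax(logits)
            onehot = np.zeros_like(probs)
            onehot[np.arange(len(yb)), yb] = 1.0
            model.backward((probs - onehot) / len(yb))
            opt.step()
            batch_losses.append(
                _bce_from_logits(logits, yb) + _l2_penalty(model, cfg.l2_lambda)
            )

        model.calibrate_batchnorm(x_train)
        val_loss = _bce_from_logits(model.forward(x_val, train=False), y_val)
        history.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(batch_losses)),
                "val_loss": val_loss,
                "lr": cfg.learning_rate,
            }
        )
        if best_val - val_loss > cfg.min_delta:
            best_val = val_loss
            best_state = model._state()
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break

    model._load_state(best_state)
    return model, history


def predict_positive_proba(
    model: MOTGNNModel, graphs: list[FeatureGraph], X_list: list[OmicsMatrix],
    idx: np.ndarray | None = None,
) -> np.ndarray:
    """Positive-class probability for the given rows of the full matrices."""
    xstars = [X.values[:, g.col_map] for X, g in zip(X_list, graphs)]
    if idx is not None:
        idx = np.asarray(idx, dtype=int)
        xstars = [x[idx] for x in xstars]
    return model.predict_proba(xstars)[:, 1]


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(
    model: MOTGNNModel, graphs: list[FeatureGraph], cfg: TrainingConfig,
    directory: str | Path,
) -> None:
    """Write a versioned checkpoint directory: a JSON manifest with the
    configuration and graph layout, plus the weight arrays."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": 1,
        "config": asdict(cfg),
        "modalities": [
            {"modality_id": g.modality_id, "nodes": g.nodes, "col_map": g.col_map}
            for g in graphs
        ],
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    arrays = {f"param_{i}": p.value for i, p in enumerate(model.params())}
    for mi, g in enumerate(graphs):
        arrays[f"adjacency_{mi}"] = g.adjacency
    buf_i = 0
    for enc in model.encoders:
        for block in enc.blocks:
            arrays[f"bn_mean_{buf_i}"] = block[1].running_mean
            arrays[f"bn_var_{buf_i}"] = block[1].running_var
            buf_i += 1
    arrays[f"bn_mean_{buf_i}"] = model.fusion.bn.running_mean
    arrays[f"bn_var_{buf_i}"] = model.fusion.bn.running_var
    np.savez(directory / "weights.npz", **arrays)


def load_checkpoint(
    directory: str | Path,
) -> tuple[MOTGNNModel, list[FeatureGraph], TrainingConfig]:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    cfg = TrainingConfig(**manifest["config"])
    data = np.load(directory / "weights.npz")
    graphs = []
    for mi, mod in enumerate(manifest["modalities"]):
        adjacency = data[f"adjacency_{mi}"]
        nodes = list(mod["nodes"])
        edges = {
            (min(nodes[i], nodes[j]), max(nodes[i], nodes[j]))
            for i in range(len(nodes))
            for j in range(i, len(nodes))
            if adjacency[i, j]
        }
        graphs.append(
            FeatureGraph(
                modality_id=mod["modality_id"],
                nodes=nodes,
                edges=edges,
                adjacency=adjacency.astype(int),
                col_map=list(mod["col_map"]),
            )
        )
    model = build_motgnn(graphs, cfg)
    for i, p in enumerate(model.params()):
        p.value = data[f"param_{i}"]
    buf_i = 0
    for enc in model.encoders:
        for block in enc.blocks:
            block[1].running_mean = data[f"bn_mean_{buf_i}"]
            block[1].running_var = data[f"bn_var_{buf_i}"]
            buf_i += 1
    model.fusion.bn.running_mean = data[f"bn_mean_{buf_i}"]
    model.fusion.bn.running_var = data[f"bn_var_{buf_i}"]
    return model, graphs, cfg
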