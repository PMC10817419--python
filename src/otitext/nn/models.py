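"""The five text-classification architectures and their logit-mean ensemble.

All architectures share the input encoding, a trainable embedding first
hidden layer, and a six-neuron linear output whose logits are passed
through softmax at prediction time.  Every hidden stage follows the order
layer -> batch normalization -> dropout.  The variants:

0. simple embedding — no convolutions, global average pooling;
1. single-kernel CNN — one convolutional layer;
2. sequential single-kernel CNN — two convolutional layers in sequence;
3. multiple parallel-kernel CNN — one concatenation of parallel convolutions;
4. deep multiple parallel-kernel CNN — two stacked parallel concatenations.

The ensemble averages the members' pre-softmax logits element-wise, applies
softmax once, and predicts the arg-max (lowest index on ties).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ..classes import N_CLASSES, OtitisClass
from ..embeddings import EmbeddingTable
from ..preprocessing import EncodedRecord
from .layers import (
    Adam,
    BatchNorm,
    Conv1D,
    Dense,
    Dropout,
    Embedding,
    GlobalAvgPool,
    GlobalMaxPool,
    Layer,
    ParallelConv,
    cross_entropy,
    softmax,
)

ARCH_NAMES = {
    0: "simple_embedding",
    1: "single_kernel_cnn",
    2: "sequential_cnn",
    3: "parallel_cnn",
    4: "deep_parallel_cnn",
}

#: Hyperparameter grid explored for every architecture.
BATCH_SIZE_GRID: tuple[int, ...] = (8, 16)
HIDDEN_DROPOUT_GRID: tuple[float, ...] = (0.5, 0.7)


@dataclass
class ArchitectureSpec:
    """Declarative description of one network variant.

    ``kernel_widths`` holds one list of widths per convolutional stage;
    parallel stages have several widths, sequential stages exactly one.
    """

    arch_id: int
    kernel_widths: list[list[int]] = field(default_factory=list)
    filters_per_kernel: int = 64
    pooling: str = "global-max"

    def __post_init__(self) -> None:
        if self.arch_id not in ARCH_NAMES:
            raise ValueError(f"arch_id must be 0-4, got {self.arch_id}")
        n_stages = len(self.kernel_widths)
        widths_ok = {
            0: n_stages == 0,
            1: n_stages == 1 and len(self.kernel_widths[0]) == 1,
            2: n_stages == 2 and all(len(w) == 1 for w in self.kernel_widths),
            3: n_stages == 1 and len(self.kernel_widths[0]) > 1,
            4: n_stages == 2 and all(len(w) > 1 for w in self.kernel_widths),
        }[self.arch_id]
        if not widths_ok:
            raise ValueError(
                f"kernel_widths {self.kernel_widths} invalid for architecture "
                f"{self.arch_id} ({ARCH_NAMES[self.arch_id]})"
            )

    @property
    def name(self) -> str:
        return ARCH_NAMES[self.arch_id]


def default_spec(arch_id: int, filters: int = 64) -> ArchitectureSpec:
    """Standard multi-kernel text-convolution defaults, fully overridable."""
    widths = {
        0: [],
        1: [[5]],
        2: [[5], [3]],
        3: [[3, 4, 5]],
        4: [[3, 4, 5], [3, 4, 5]],
    }[arch_id]
    f = {0: filters, 1: 2 * filters, 2: 2 * filters, 3: filters, 4: filters}[arch_id]
    return ArchitectureSpec(arch_id=arch_id, kernel_widths=widths, filters_per_kernel=f)


@dataclass
class TrainingConfig:
    batch_size: int = 16
    embedding_dropout: float = 0.2
    hidden_dropout: float = 0.5
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    max_epochs: int = 50
    patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        for r in (self.embedding_dropout, self.hidden_dropout):
            if not 0.0 <= r < 1.0:
                raise ValueError("dropout rates must be in [0, 1)")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be >= 0")


class Network:
    """A sequential stack of layers mapping (B, L) index tensors to logits."""

    def __init__(self, layers: list[Layer], rng: np.random.Generator) -> None:
        self.layers = layers
        self.rng = rng

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def snapshot(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def restore(self, values: list[np.ndarray]) -> None:
        for p, v in zip(self.params(), values):
            p.value[...] = v


def build_model(
    spec: ArchitectureSpec,
    embedding: EmbeddingTable,
    training: TrainingConfig,
) -> Network:
    """Assemble the untrained network for one architecture.

    The embedding layer is initialized from the skip-gram table and
    fine-tuned during supervised training; every hidden stage is followed by
    batch normalization then dropout (0.2 after the embedding, the
    configured hidden rate elsewhere).
    """
    rng = np.random.default_rng(training.seed)
    d = embedding.dimension
    layers: list[Layer] = [
        Embedding(embedding.matrix),
        BatchNorm(d),
        Dropout(training.embedding_dropout, rng),
    ]
    in_channels = d
    for stage_widths in spec.kernel_widths:
        convs = [
            Conv1D(in_channels, spec.filters_per_kernel, w, rng) for w in stage_widths
        ]
        stage: Layer = convs[0] if len(convs) == 1 else ParallelConv(convs)
        out_channels = spec.filters_per_kernel * len(stage_widths)
        layers += [stage, BatchNorm(out_channels), Dropout(training.hidden_dropout, rng)]
        in_channels = out_channels
    if spec.arch_id == 0:
        layers.append(GlobalAvgPool())
    else:
        layers.append(GlobalMaxPool())
    layers.append(Dense(in_channels, N_CLASSES, rng))
    return Network(layers, rng)


@dataclass
class TrainedModel:
    network: Network
    spec: Optional[ArchitectureSpec]
    config: TrainingConfig
    history: dict

    def metadata(self) -> dict:
        return {
            "architecture": self.spec.name if self.spec else None,
            "arch_id": self.spec.arch_id if self.spec else None,
            "kernel_widths": self.spec.kernel_widths if self.spec else None,
            "filters_per_kernel": self.spec.filters_per_kernel if self.spec else None,
            "batch_size": self.config.batch_size,
            "hidden_dropout": self.config.hidden_dropout,
            "embedding_dropout": self.config.embedding_dropout,
            "seed": self.config.seed,
            "history": self.history,
        }

    def save_metadata(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.metadata(), fh, indent=2)


def stack_encoded(
    records: Sequence[EncodedRecord], require_labels: bool = True
) -> tuple[np.ndarray, Optional[np.ndarray]]:
    X = np.stack([r.indices for r in records]) if records else np.empty((0, 0), dtype=np.int64)
    labels = [r.label for r in records]
    if any(l is None for l in labels):
        if require_labels:
            raise ValueError("encoded records are missing labels")
        return X, None
    y = np.array([l.index for l in labels], dtype=np.int64)
    return X, y


def train_model(
    network: Network,
    train_records: Sequence[EncodedRecord],
    config: TrainingConfig,
    monitor_records: Sequence[EncodedRecord] | None = None,
) -> TrainedModel:
    """Fit with Adam on mini-batch mean cross-entropy.

    With a monitor set, training stops early after ``patience`` epochs
    without validation-loss improvement and the best-epoch weights are
    restored.  Deterministic given the seed (single-threaded execution).
    """
    if not train_records:
        raise ValueError("training set must be non-empty")
    X, y = stack_encoded(train_records)
    Xm = ym = None
    if monitor_records:
        Xm, ym = stack_encoded(monitor_records)
    rng = np.random.default_rng(config.seed + 1)
    opt = Adam(network.params(), config.learning_rate, config.beta1, config.beta2)
    history: dict = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_snapshot = None
    stale = 0
    n = len(train_records)
    for _epoch in range(config.max_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            logits = network.forward(X[idx], train=True)
            loss, dlogits = cross_entropy(logits, y[idx])
            opt.zero_grad()
            network.backward(dlogits)
            opt.step()
            losses.append(loss)
        history["train_loss"].append(float(np.mean(losses)))
        if Xm is not None:
            val_logits = _forward_batched(network, Xm)
            val_loss, _ = cross_entropy(val_logits, ym)
            history["val_loss"].append(float(val_loss))
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_snapshot = network.snapshot()
                stale = 0
            else:
                stale += 1
                if stale >= config.patience:
                    break
    if best_snapshot is not None:
        network.restore(best_snapshot)
    return TrainedModel(network=network, spec=None, config=config, history=history)


def _forward_batched(network: Network, X: np.ndarray, batch: int = 256) -> np.ndarray:
    outs = [network.forward(X[s : s + batch], train=False) for s in range(0, len(X), batch)]
    return np.concatenate(outs, axis=0) if outs else np.empty((0, N_CLASSES))


def predict_logits(model: TrainedModel | Network, records: Sequence[EncodedRecord]) -> np.ndarray:
    """Pre-softmax (n, 6) logit matrix, deterministic per model."""
    network = model.network if isinstance(model, TrainedModel) else model
    if not records:
        return np.empty((0, N_CLASSES))
    X, _ = stack_encoded(records, require_labels=False)
    emb = network.layers[0]
    if isinstance(emb, Embedding) and X.max(initial=0) >= emb.W.value.shape[0]:
        raise ValueError("record indices exceed the model's vocabulary")
    logits = _forward_batched(network, X)
    if not np.isfinite(logits).all():
        raise ValueError("model produced non-finite logits")
    return logits


def ensemble_predict(
    logit_matrices: Sequence[np.ndarray],
) -> tuple[list[OtitisClass], np.ndarray]:
    """Average member logits, softmax once, arg-max with lowest-index ties.

    Returns (predicted classes, per-class probability matrix).
    """
    if not logit_matrices:
        raise ValueError("ensemble needs at least one logit matrix")
    shapes = {m.shape for m in logit_matrices}
    if len(shapes) != 1:
        raise ValueError(f"logit matrices have mismatched shapes: {sorted(shapes)}")
    (shape,) = shapes
    if len(shape) != 2 or shape[1] != N_CLASSES:
        raise ValueError(f"logit matrices must be (n, {N_CLASSES}), got {shape}")
    mean = np.mean(logit_matrices, axis=0)
    probs = softmax(mean)
    preds = [OtitisClass(int(i)) for i in mean.argmax(axis=1)]
    return preds, probs


def accuracy_of(
    model: TrainedModel | Network, records: Sequence[EncodedRecord]
) -> float:
    logits = predict_logits(model, records)
    _, y = stack_encoded(records)
    return float((logits.argmax(axis=1) == y).mean())


def default_grid(
    batch_sizes: Sequence[int] = BATCH_SIZE_GRID,
    hidden_dropouts: Sequence[float] = HIDDEN_DROPOUT_GRID,
) -> list[dict]:
    return [
        {"batch_size": m, "hidden_dropout": d}
        for m in batch_sizes
        for d in hidden_dropouts
    ]


def two_stage_develop(
    specs: Sequence[ArchitectureSpec],
    embedding: EmbeddingTable,
    train_records: Sequence[EncodedRecord],
    validation_records: Sequence[EncodedRecord],
    grid: Sequence[dict] | None = None,
    n_transfer: int = 300,
    base_config: TrainingConfig | None = None,
    seed: int = 0,
) -> dict[int, dict]:
    """Two-stage model development.

    Stage 1 trains every grid configuration per architecture on the
    training set and selects the best by validation accuracy (ties to the
    earlier grid point).  Stage 2 retrains the selected configuration on
    the training set plus a seeded sample of ``n_transfer`` validation
    records (without replacement), then re-measures validation accuracy.
    Returns {arch_id: {"model": TrainedModel, "trace": [...],
    "validation_accuracy": float}}.
    """
    if grid is None:
        grid = default_grid()
    if not grid:
        raise ValueError("hyperparameter grid must be non-empty")
    if len(validation_records) < n_transfer:
        raise ValueError(
            f"validation set has {len(validation_records)} records; "
            f"n_transfer={n_transfer} requires at least that many"
        )
    base = base_config or TrainingConfig()
    rng = np.random.default_rng(seed)
    transfer_idx = rng.choice(len(validation_records), size=n_transfer, replace=False)
    transfer = [validation_records[int(i)] for i in sorted(transfer_idx)]
    stage2_train = list(train_records) + transfer

    results: dict[int, dict] = {}
    for spec in specs:
        trace = []
        best = None
        for gi, point in enumerate(grid):
            cfg = _with(base, point, seed, spec.arch_id, gi)
            net = build_model(spec, embedding, cfg)
            trained = train_model(net, train_records, cfg, monitor_records=validation_records)
            trained.spec = spec
            acc = accuracy_of(trained, validation_records)
            trace.append({"stage": 1, "point": dict(point), "validation_accuracy": acc})
            if best is None or acc > best[0]:
                best = (acc, point, cfg)
        _, best_point, best_cfg = best
        net = build_model(spec, embedding, best_cfg)
        final = train_model(net, stage2_train, best_cfg, monitor_records=validation_records)
        final.spec = spec
        final_acc = accuracy_of(final, validation_records)
        trace.append({"stage": 2, "point": dict(best_point), "validation_accuracy": final_acc})
        results[spec.arch_id] = {
            "model": final,
            "trace": trace,
            "validation_accuracy": final_acc,
        }
    return results


def _with(base: TrainingConfig, point: dict, seed: int, arch_id: int, gi: int) -> TrainingConfig:
    kwargs = {
        "batch_size": base.batch_size,
        "embedding_dropout": base.embedding_dropout,
        "hidden_dropout": base.hidden_dropout,
        "learning_rate": base.learning_rate,
        "beta1": base.beta1,
        "beta2": base.beta2,
        "max_epochs": base.max_epochs,
        "patience": base.patience,
        "seed": seed * 1009 + arch_id * 101 + gi,
    }
    kwargs.update(point)
    return TrainingConfig(**kwargs)
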