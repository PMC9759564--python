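"""The 4-block VGG-style classifier and the repeated-attempt protocol.

The network has four convolutional blocks (3x3 convolution, ReLU, 2x2
max pool with stride 2) followed by a small dense head with a 2-way
softmax output. Block L carries ``floor(0.5 * L * floor(sqrt(P)))``
filters where P is the pixel count of the input image — for a square
image, floor(sqrt(P)) is just the side length.

Training uses SGD with momentum 0.88, L2 regularization 9.4e-7, batch
size 8 and up to 1000 mini-batch updates at learning rate 0.02. An
*attempt* is one full re-split / encode / train / evaluate cycle; the
experiment protocol aggregates best and average accuracy over attempts
(30 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .encoders import EncodingConfig, encode_row
from .evaluation import EvalReport, confusion, metrics
from .tabular_io import SplitSpec, TabularDataset, split

__all__ = [
    "ArchitectureSpec",
    "TrainConfig",
    "TrainedModel",
    "ExperimentReport",
    "filter_counts",
    "build_architecture",
    "build_network",
    "train",
    "run_experiment",
]

_N_BLOCKS = 4


@dataclass(frozen=True)
class ArchitectureSpec:
    """Input geometry plus the per-block filter counts it implies."""

    height: int
    width: int
    channels: int
    filters: tuple[int, ...]
    kernel: int = 3
    pool: int = 2
    head_hidden: int = 64
    n_classes: int = 2


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (defaults are the study settings)."""

    max_iterations: int = 1000
    attempts: int = 30
    learning_rate: float = 0.02
    momentum: float = 0.88
    l2: float = 9.4e-7
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.max_iterations, self.attempts, self.batch_size) < 1:
            raise ValueError("iterations, attempts and batch size must be >= 1")
        if min(self.learning_rate, self.momentum, self.l2) < 0:
            raise ValueError("rates must be non-negative")


def filter_counts(h: int, w: int) -> tuple[int, ...]:
    """floor(0.5 * L * floor(sqrt(h*w))) for blocks L = 1..4."""
    side = int(np.floor(np.sqrt(h * w)))
    return tuple(int(np.floor(0.5 * L * side)) for L in range(1, _N_BLOCKS + 1))


def build_architecture(h: int, w: int, c: int) -> ArchitectureSpec:
    """Derive the 4-block architecture for an h x w x c input."""
    if c not in (1, 3):
        raise ValueError("channels must be 1 or 3")
    if h < 16 or w < 16:
        raise ValueError(
            "image too small for four 2x2 pools; upscale the encoding to "
            "at least 16x16")
    return ArchitectureSpec(h, w, c, filter_counts(h, w))


def _pooled_size(s: int) -> int:
    for _ in range(_N_BLOCKS):
        s //= 2
    return s


def build_network(arch: ArchitectureSpec, rng: np.random.Generator) -> nn.Network:
    layers: list = []
    in_ch = arch.channels
    for f in arch.filters:
        layers += [nn.Conv2D(in_ch, f, rng), nn.ReLU(), nn.MaxPool2()]
        in_ch = f
    flat = arch.filters[-1] * _pooled_size(arch.height) * _pooled_size(arch.width)
    layers += [nn.Flatten(),
               nn.Dense(flat, arch.head_hidden, rng), nn.ReLU(),
               nn.Dense(arch.head_hidden, arch.n_classes, rng)]
    return nn.Network(layers)


@dataclass
class TrainedModel:
    network: nn.Network
    history: dict[str, list[float]]

    def predict(self, images: np.ndarray) -> np.ndarray:
        return self.network.predict(_to_nchw(images))

    def accuracy(self, images: np.ndarray, labels: np.ndarray) -> float:
        """Percent correct."""
        return float((self.predict(images) == labels).mean() * 100.0)


def _to_nchw(images: np.ndarray) -> np.ndarray:
    images = np.asarray(images, dtype=np.float32)
    if images.ndim == 3:  # B x H x W -> single channel
        images = images[:, np.newaxis]
    elif images.ndim == 4:  # B x H x W x C
        images = images.transpose(0, 3, 1, 2)
    else:
        raise ValueError("images must be BxHxW or BxHxWxC")
    return np.ascontiguousarray(images)


def train(images: np.ndarray, labels: np.ndarray,
          arch: ArchitectureSpec, cfg: TrainConfig) -> TrainedModel:
    """Fit the network with momentum SGD; deterministic given the seed.

    Mini-batches cycle through a per-epoch reshuffle until
    ``max_iterations`` update steps have run. The history records the
    batch loss at every step.
    """
    x = _to_nchw(images)
    y = np.asarray(labels, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")
    rng = np.random.default_rng(cfg.seed)
    net = build_network(arch, rng)
    opt = nn.SGDMomentum(net, cfg.learning_rate, cfg.momentum, cfg.l2)
    n = x.shape[0]
    losses: list[float] = []
    order = rng.permutation(n)
    pos = 0
    for _ in range(cfg.max_iterations):
        if pos >= n:
            order = rng.permutation(n)
            pos = 0
        idx = order[pos:pos + cfg.batch_size]
        pos += cfg.batch_size
        loss = net.loss_and_grad(x[idx], y[idx])
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite loss at step {len(losses)}")
        losses.append(loss)
        opt.step()
    model = TrainedModel(net, {"loss": losses})
    model.history["train_accuracy"] = [model.accuracy(images, y)]
    return model


@dataclass
class ExperimentReport:
    """Per-attempt accuracies (percent) and test-set diagnostic reports."""

    val_accuracies: list[float]
    test_accuracies: list[float]
    test_reports: list[EvalReport]

    @property
    def best_val(self) -> float:
        return max(self.val_accuracies)

    @property
    def best_test(self) -> float:
        return max(self.test_accuracies)

    @property
    def mean_val(self) -> float:
        return float(np.mean(self.val_accuracies))

    @property
    def mean_test(self) -> float:
        return float(np.mean(self.test_accuracies))


def _encode_partition(part: TabularDataset, cfg: EncodingConfig) -> np.ndarray:
    imgs = [encode_row(part.features[i], cfg).pixels
            for i in range(part.n_rows)]
    return np.stack(imgs).astype(np.float32)


def run_experiment(ds: TabularDataset, enc_cfg: EncodingConfig,
                   cfg: TrainConfig,
                   split_spec: SplitSpec | None = None) -> ExperimentReport:
    """Run the repeated-attempt protocol on a prepared dataset.

    Each attempt re-splits the data with an attempt-specific seed
    (``cfg.seed + attempt``), encodes the partitions, builds the
    architecture from the encoded image geometry, trains, and evaluates
    accuracy on validation and test plus the diagnostic metrics on test.
    """
    if not ds.normalized:
        raise ValueError("normalize the dataset before running the experiment")
    base = split_spec or SplitSpec()
    val_acc: list[float] = []
    test_acc: list[float] = []
    reports: list[EvalReport] = []
    for attempt in range(cfg.attempts):
        seed = cfg.seed + attempt
        spec = SplitSpec(base.test_fraction, base.validation_fraction_of_train,
                         seed=seed, stratified=base.stratified)
        tr, va, te = split(ds, spec)
        x_tr = _encode_partition(tr, enc_cfg)
        x_va = _encode_partition(va, enc_cfg)
        x_te = _encode_partition(te, enc_cfg)
        h, w = x_tr.shape[1:3]
        c = x_tr.shape[3] if x_tr.ndim == 4 else 1
        arch = build_architecture(h, w, c)
        model = train(x_tr, tr.labels, arch,
                      TrainConfig(cfg.max_iterations, 1, cfg.learning_rate,
                                  cfg.momentum, cfg.l2, cfg.batch_size, seed))
        val_acc.append(model.accuracy(x_va, va.labels))
        test_acc.append(model.accuracy(x_te, te.labels))
        reports.append(metrics(confusion(te.labels, model.predict(x_te))))
    return ExperimentReport(val_acc, test_acc, reports)
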