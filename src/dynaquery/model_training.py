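"""Classifier contract, loss, per-epoch training loop, and LR scheduling.

The classifier is a pluggable image backbone (any feature extractor obeying
the ``forward/backward/params`` layer contract) whose features are
concatenated with the logistic-normalized metadata vector and passed through
a fusion head of two dense layers (128 and 56 nodes) to 2 logits.  Training
uses softmax cross-entropy, SGD with Nesterov momentum 0.95, L2 weight decay
1e-2, and a reduce-on-plateau learning-rate schedule (×0.9 after a 20-epoch
stall of the training loss).

The default backbone is a compact convolutional network sized so the whole
framework trains in seconds on one CPU; a large pretrained residual network
can be dropped in behind the same contract when available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import nnet
from .preprocessing import TARGET_HEIGHT, TARGET_WIDTH, AugmentationParams, augment_batch


@dataclass
class OptimizerConfig:
    """Optimizer and LR-schedule hyperparameters (defaults as tuned by grid
    search: lr 1e-2, weight decay 1e-2)."""

    learning_rate_init: float = 1e-2
    momentum: float = 0.95
    nesterov: bool = True
    weight_decay: float = 1e-2
    gamma: float = 0.9
    plateau_patience_epochs: int = 20
    minibatch_size: int = 16

    def __post_init__(self) -> None:
        if self.learning_rate_init < 0 or self.gamma <= 0 or self.weight_decay < 0:
            raise ValueError("rates must be non-negative (gamma positive)")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")
        if self.minibatch_size < 1 or self.plateau_patience_epochs < 1:
            raise ValueError("minibatch_size and patience must be >= 1")


@dataclass
class LossHistory:
    """Per-epoch mean training loss plus the epochs at which queries occurred.

    Epochs are 1-based; ``query_epochs`` starts with 0, the initialization
    event.  This object is the dynamic query scheduler's sole input.
    """

    per_epoch_loss: list[float] = field(default_factory=list)
    query_epochs: list[int] = field(default_factory=lambda: [0])

    def __post_init__(self) -> None:
        if any(l < 0 for l in self.per_epoch_loss):
            raise ValueError("losses must be non-negative")
        if not self.query_epochs or self.query_epochs[0] != 0:
            raise ValueError("query_epochs must start with the epoch-0 initialization event")
        if any(b <= a for a, b in zip(self.query_epochs, self.query_epochs[1:])):
            raise ValueError("query_epochs must be strictly increasing")

    @property
    def n_epochs(self) -> int:
        return len(self.per_epoch_loss)

    def record_epoch(self, loss: float) -> None:
        if loss < 0:
            raise ValueError("loss must be non-negative")
        self.per_epoch_loss.append(float(loss))

    def record_query(self, epoch: int) -> None:
        if epoch <= self.query_epochs[-1]:
            raise ValueError("query epochs must be strictly increasing")
        self.query_epochs.append(int(epoch))

    def epochs_since_last_query(self) -> int:
        return self.n_epochs - self.query_epochs[-1]


def softmax(logits: np.ndarray) -> np.ndarray:
    """Exponential normalization of logits into a probability vector (or a
    batch of them along the last axis); shift-invariant and overflow-safe."""
    logits = np.asarray(logits, dtype=float)
    if not np.all(np.isfinite(logits)):
        raise ValueError("logits must be finite")
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, truth: np.ndarray) -> float:
    """−ln of the probability assigned to the true class (one-hot ``truth``).

    Natural log, so chance level for two classes is ln 2 ≈ 0.693; a zero
    true-class probability is epsilon-clamped (1e-12) rather than infinite.
    """
    probs = np.asarray(probs, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if probs.shape != truth.shape:
        raise ValueError("probs and truth must have equal shape")
    if np.any(probs < -1e-9) or abs(probs.sum() - 1.0) > 1e-6:
        raise ValueError("probs is not a probability vector")
    if not (set(np.round(truth, 12)) <= {0.0, 1.0}) or truth.sum() != 1.0:
        raise ValueError("truth must be one-hot")
    p_true = float(probs[truth.argmax()])
    return -math.log(max(p_true, 1e-12))


def make_backbone(name: str, rng: np.random.Generator) -> tuple[nnet.Sequential, int, int]:
    """Build a named image backbone; returns (network, feature_dim, pool_factor).

    ``tinyconv``: an 8× average-pool front end (applied outside the gradient
    graph — it has no parameters), one 3×3 conv with 8 channels, ReLU,
    2× max-pool, flatten → 792 features from a 160×200 input.
    """
    if name == "tinyconv":
        pool = 8
        net = nnet.Sequential(
            nnet.Conv2d(1, 8, 3, rng, first=True),
            nnet.ReLU(),
            nnet.MaxPool(2),
            nnet.Flatten(),
        )
        h = (TARGET_HEIGHT // pool - 2) // 2
        w = (TARGET_WIDTH // pool - 2) // 2
        return net, 8 * h * w, pool
    raise ValueError(f"unknown backbone {name!r}")


class ClassifierModel:
    """Image backbone + metadata fusion head producing 2 class logits."""

    def __init__(self, metadata_dim: int, backbone: str = "tinyconv", seed: int = 0):
        rng = np.random.default_rng(seed)
        self.metadata_dim = metadata_dim
        self.backbone_name = backbone
        self.backbone, self.feature_dim, self.pool_factor = make_backbone(backbone, rng)
        self.head = nnet.Sequential(
            nnet.Dense(self.feature_dim + metadata_dim, 128, rng),
            nnet.ReLU(),
            nnet.Dense(128, 56, rng),
            nnet.ReLU(),
            nnet.Dense(56, 2, rng),
        )

    def params(self) -> list[nnet.Parameter]:
        return self.backbone.params() + self.head.params()

    def pool_images(self, images: np.ndarray) -> np.ndarray:
        """Fixed average-pool front end: (N, H, W) → (N, 1, H/k, W/k).

        Parameter-free, so callers may cache the result for repeated
        inference (e.g. the per-epoch validation pass)."""
        k = self.pool_factor
        n, h, w = images.shape
        x = np.ascontiguousarray(images, dtype=nnet.DTYPE)
        return (x.reshape(n, h // k, k, w // k, k).sum(axis=4).sum(axis=2) / (k * k))[:, None]

    def forward(self, images: np.ndarray, metadata: np.ndarray) -> np.ndarray:
        """Logits for a batch: images (N, H, W) — or already pooled
        (N, 1, h, w) — plus metadata (N, M) → (N, 2)."""
        pooled = self.pool_images(images) if images.ndim == 3 else images
        feats = self.backbone.forward(pooled)
        meta = np.asarray(metadata, dtype=nnet.DTYPE)
        return self.head.forward(np.concatenate([feats, meta], axis=1))

    def backward(self, grad_logits: np.ndarray) -> None:
        grad = self.head.backward(grad_logits)
        self.backbone.backward(grad[:, : self.feature_dim])

    def predict_proba(self, images: np.ndarray, metadata: np.ndarray) -> np.ndarray:
        return softmax(self.forward(images, metadata))

    # --- portable checkpointing -------------------------------------------
    def save(self, path) -> None:
        arrays = {f"p{i}": p.value for i, p in enumerate(self.params())}
        np.savez(
            path,
            __meta__=np.array([self.metadata_dim], dtype=np.int64),
            __backbone__=np.array(self.backbone_name),
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "ClassifierModel":
        data = np.load(path, allow_pickle=False)
        model = cls(int(data["__meta__"][0]), backbone=str(data["__backbone__"]))
        for i, p in enumerate(model.params()):
            p.value[...] = data[f"p{i}"]
        return model


def train_epoch(
    model: ClassifierModel,
    samples: list[tuple[np.ndarray, np.ndarray, int]],
    optimizer: nnet.SGDNesterov,
    config: OptimizerConfig,
    rng: np.random.Generator,
    augmentation: AugmentationParams | None = AugmentationParams(),
) -> float:
    """One pass over the labeled pool; returns the mean minibatch loss.

    ``samples`` holds prepared triples (image 160×200 in [−1,1], normalized
    metadata, class index).  Samples are shuffled, augmented once each (when
    ``augmentation`` is given), and consumed in minibatches of
    min(minibatch_size, pool size).
    """
    if not samples:
        raise ValueError("labeled pool is empty")
    order = rng.permutation(len(samples))
    batch_size = min(config.minibatch_size, len(samples))
    losses = []
    for start in range(0, len(samples), batch_size):
        idx = order[start : start + batch_size]
        x = np.stack([samples[i][0] for i in idx]).astype(np.float32, copy=False)
        if augmentation is not None:
            x = augment_batch(x, augmentation, rng)
        m = np.stack([samples[i][1] for i in idx])
        y = np.zeros((len(idx), 2))
        y[np.arange(len(idx)), [samples[i][2] for i in idx]] = 1.0
        logits = model.forward(x, m)
        probs = softmax(logits)
        loss = float(-(y * np.log(np.clip(probs, 1e-12, None))).sum(axis=1).mean())
        optimizer.zero_grad()
        model.backward((probs - y) / len(idx))
        optimizer.step()
        losses.append(loss)
    return float(np.mean(losses))


def update_learning_rate(
    current_lr: float, history: LossHistory, config: OptimizerConfig, start_epoch: int = 0
) -> float:
    """Reduce-on-plateau: multiply the LR by gamma when the training loss has
    not improved on its running best for ``plateau_patience_epochs`` epochs.

    The rule is evaluated by replaying the history (best-so-far with a bad-
    epoch counter that resets after each reduction), so consecutive 20-epoch
    stalls compound: two stalls give gamma².  Returns the (possibly) reduced
    rate for the most recent epoch.

    ``start_epoch`` scopes the replay: during active learning the caller
    passes the last query epoch, because a query changes the training set
    and makes earlier losses incomparable — a loss actively decreasing from
    its post-query spike is not a plateau even if it never beats the minimum
    reached while overfitting a smaller pool.
    """
    losses = history.per_epoch_loss[start_epoch:]
    if not losses:
        raise ValueError("loss history is empty")
    best = math.inf
    bad = 0
    fired_at_end = False
    for i, loss in enumerate(losses):
        if loss < best:
            best = loss
            bad = 0
        else:
            bad += 1
        if bad >= config.plateau_patience_epochs:
            bad = 0
            fired_at_end = i == len(losses) - 1
    return current_lr * config.gamma if fired_at_end else current_lr
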