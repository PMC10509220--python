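"""Entropy-based query selection, the dynamic query scheduler, and the outer
active-learning loop.

The scheduler is the central idea: instead of querying the oracle every Q
epochs (fixed schedule), *dynamic querying* watches the training-loss history
and asks for a new label when learning from the current labeled pool has
become unproductive.  A query fires when either

1. the simple moving average of the 5 most recent per-epoch training losses
   drops strictly below 1e-4 (the model is memorizing its pool), or
2. at least 20 epochs have passed since the previous query and the loss has
   plateaued: the mean loss of the most recent 25% of the epochs since the
   last query exceeds half the mean loss of the preceding 75%.

Query *selection* is uncertainty sampling: among a random candidate subset of
the unlabeled pool (default 500), the sample(s) whose predicted class
distribution has the highest Shannon entropy (base 2) are queried.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import data_pools
from .data_pools import LABEL_TO_INDEX, Dataset, PoolState, initialize_labeled, split_dataset
from .model_training import (
    ClassifierModel,
    LossHistory,
    OptimizerConfig,
    train_epoch,
    update_learning_rate,
)
from .nnet import SGDNesterov
from .preprocessing import AugmentationParams, augment_batch, preprocess


@dataclass
class SchedulerConfig:
    """When to query.  ``dynamic`` uses the two loss-driven conditions;
    ``fixed`` queries every ``fixed_interval`` epochs; ``random_timing``
    queries each epoch with probability 1/``fixed_interval`` (a baseline
    matched in expected frequency to the fixed schedule)."""

    mode: Literal["dynamic", "fixed", "random_timing"] = "dynamic"
    sma_window: int = 5
    sma_threshold: float = 1e-4
    min_epochs_between_queries: int = 20
    recent_fraction: float = 0.25
    plateau_ratio: float = 0.5
    fixed_interval: int = 25

    def __post_init__(self) -> None:
        if self.sma_window < 1:
            raise ValueError("sma_window must be >= 1")
        if not 0 < self.recent_fraction < 1:
            raise ValueError("recent_fraction must be in (0, 1)")
        if self.plateau_ratio <= 0 or self.fixed_interval < 1:
            raise ValueError("plateau_ratio must be positive, fixed_interval >= 1")


@dataclass
class QueryPolicyConfig:
    """What to query: score a random subset of the unlabeled pool (candidate
    pool) and take the top entropy sample(s), or pick at random."""

    candidate_pool_size: int = 500
    query_batch_size: int = 1
    selection: Literal["entropy", "random"] = "entropy"

    def __post_init__(self) -> None:
        if not 1 <= self.query_batch_size <= self.candidate_pool_size:
            raise ValueError("need 1 <= query_batch_size <= candidate_pool_size")


@dataclass(frozen=True)
class QueryEvent:
    """One query: when it happened, which condition fired, what was chosen.

    The epoch-0 initialization event uses condition ``initial`` and NaN
    entropies (nothing was scored)."""

    epoch: int
    condition_fired: Literal["sma_threshold", "plateau", "fixed", "random", "initial"]
    sample_ids: list[str]
    entropies: list[float]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.entropies):
            raise ValueError("sample_ids and entropies must have equal length")

    def to_json(self) -> str:
        return json.dumps(
            {
                "epoch": self.epoch,
                "condition": self.condition_fired,
                "sample_ids": list(self.sample_ids),
                "entropies": [None if math.isnan(e) else e for e in self.entropies],
            }
        )


@dataclass
class ALRunConfig:
    """Everything one active-learning run needs."""

    query_budget: int = 30
    max_epochs: int = 1000
    n_initial: int = 1
    per_class_cap: int = 50
    seed: int = 0
    stop_patience: int = 100
    backbone: str = "tinyconv"
    scheduler: SchedulerConfig = field(default_factory=SchedulerConfig)
    policy: QueryPolicyConfig = field(default_factory=QueryPolicyConfig)
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    augmentation: AugmentationParams = field(default_factory=AugmentationParams)

    def __post_init__(self) -> None:
        if self.query_budget < 0 or self.max_epochs < 1:
            raise ValueError("query_budget must be >= 0 and max_epochs >= 1")


def entropy(probs: Sequence[float] | np.ndarray) -> float:
    """Shannon entropy, base 2, of a class probability vector; for two
    classes H ∈ [0, 1], maximal at (0.5, 0.5) and zero at a one-hot vector
    (with the 0·log₂0 := 0 convention)."""
    p = np.asarray(probs, dtype=float)
    if p.ndim != 1 or p.size < 2 or np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("not a probability vector")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum()) + 0.0


def select_candidates(
    unlabeled: Sequence[str], candidate_pool_size: int, rng: np.random.Generator | int
) -> list[str]:
    """Uniform sample (without replacement) of unlabeled ids to score; when
    the pool is smaller than the requested size, the whole pool is returned
    (querying then picks the absolute highest entropy)."""
    ids = sorted(unlabeled)
    if not ids:
        raise ValueError("unlabeled pool is empty")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if candidate_pool_size >= len(ids):
        return ids
    return list(rng.choice(ids, size=candidate_pool_size, replace=False))


def select_query_samples(
    model: ClassifierModel,
    candidates: dict[str, tuple[np.ndarray, np.ndarray]],
    query_batch_size: int,
    rng: np.random.Generator | int | None = None,
    augmentation: AugmentationParams | None = AugmentationParams(),
) -> tuple[list[str], list[float]]:
    """Score candidates by predictive entropy and return the top batch.

    ``candidates`` maps sample_id → (prepared image, normalized metadata).
    Each candidate gets one augmentation draw before scoring (mirroring the
    training-time input distribution).  Ties break by ascending sample_id.
    """
    if not candidates:
        raise ValueError("candidate set is empty")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    ids = sorted(candidates)
    imgs = np.stack([candidates[sid][0] for sid in ids])
    if augmentation is not None:
        imgs = augment_batch(imgs, augmentation, rng)
    metas = np.stack([candidates[sid][1] for sid in ids])
    probs = model.predict_proba(imgs, metas)
    scores = [entropy(p) for p in probs]
    order = sorted(range(len(ids)), key=lambda i: (-scores[i], ids[i]))
    top = order[: min(query_batch_size, len(ids))]
    return [ids[i] for i in top], [scores[i] for i in top]


def condition_sma(history: LossHistory, config: SchedulerConfig) -> bool:
    """Condition 1: SMA of the last ``sma_window`` epoch losses strictly
    below ``sma_threshold``.  False while fewer epochs have been recorded."""
    losses = history.per_epoch_loss
    if len(losses) < config.sma_window:
        return False
    return float(np.mean(losses[-config.sma_window :])) < config.sma_threshold


def condition_plateau(history: LossHistory, config: SchedulerConfig) -> bool:
    """Condition 2: at least 20 epochs since the previous query, and the mean
    loss of the most recent 25% of those epochs exceeds ``plateau_ratio``
    (half) of the mean of the preceding 75%.

    Both segments are scoped to the k epochs since the last query event;
    the recent segment has ceil(recent_fraction · k) epochs.
    """
    t = history.n_epochs
    last_q = history.query_epochs[-1]
    k = t - last_q
    if k < config.min_epochs_between_queries:
        return False
    segment = history.per_epoch_loss[last_q:t]
    r = math.ceil(config.recent_fraction * k)
    recent, preceding = segment[-r:], segment[:-r]
    if not preceding:
        return False
    return float(np.mean(recent)) > config.plateau_ratio * float(np.mean(preceding))


def should_query(
    history: LossHistory,
    epoch: int,
    config: SchedulerConfig,
    rng: np.random.Generator | None = None,
) -> tuple[bool, str | None]:
    """Decide whether to query at the end of ``epoch``; returns the decision
    and the tag of the condition that fired (Condition 1 takes precedence)."""
    if config.mode == "dynamic":
        if condition_sma(history, config):
            return True, "sma_threshold"
        if condition_plateau(history, config):
            return True, "plateau"
        return False, None
    if config.mode == "fixed":
        if epoch - history.query_epochs[-1] == config.fixed_interval:
            return True, "fixed"
        return False, None
    if config.mode == "random_timing":
        if rng is None:
            raise ValueError("random_timing mode needs a random generator")
        if rng.random() < 1.0 / config.fixed_interval:
            return True, "random"
        return False, None
    raise ValueError(f"unknown scheduler mode {config.mode!r}")


@dataclass
class ALResult:
    """Outcome of one active-learning (or fully-supervised) run."""

    learning_curve: pd.DataFrame
    query_log: list[QueryEvent]
    model: ClassifierModel
    pool: PoolState
    history: LossHistory
    split: data_pools.SplitResult


def _prepare_all(dataset: Dataset) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Run the deterministic preprocessing once per sample and cache it."""
    prepared = {}
    for sample in dataset:
        img, meta = preprocess(sample)
        prepared[sample.sample_id] = (img.astype(np.float32), meta.normalized)
    return prepared


def run_active_learning(dataset: Dataset, config: ALRunConfig) -> ALResult:
    """The outer loop: split → initialize one labeled sample → train epoch by
    epoch, recording loss and validation accuracy, querying the oracle when
    the scheduler fires, until the budget is spent and performance has
    stabilized (``stop_patience`` epochs without a validation-accuracy
    improvement) or ``max_epochs`` is reached.

    Each concern draws from its own seeded stream (split, pool init, model
    init, minibatch shuffling/augmentation, candidate choice, scoring
    augmentation, random timing/selection), so e.g. changing the candidate
    pool size does not perturb the split.
    """
    streams = np.random.SeedSequence(config.seed).spawn(8)
    seed_of = lambda i: int(streams[i].generate_state(1)[0] % (2**31))
    rng_train = np.random.default_rng(streams[3])
    rng_candidates = np.random.default_rng(streams[4])
    rng_scoring = np.random.default_rng(streams[5])
    rng_timing = np.random.default_rng(streams[6])
    rng_random_sel = np.random.default_rng(streams[7])

    split = split_dataset(dataset, config.per_class_cap, seed_of(0))
    pool = initialize_labeled(dataset, split, config.n_initial, seed_of(1))
    prepared = _prepare_all(dataset)

    metadata_dim = len(next(iter(prepared.values()))[1])
    model = ClassifierModel(metadata_dim, backbone=config.backbone, seed=seed_of(2))
    optimizer = SGDNesterov(
        model.params(),
        lr=config.optimizer.learning_rate_init,
        momentum=config.optimizer.momentum,
        weight_decay=config.optimizer.weight_decay,
        nesterov=config.optimizer.nesterov,
    )

    val_ids = sorted(split.validation)
    val_x = np.stack([prepared[sid][0] for sid in val_ids])
    val_pooled = model.pool_images(val_x)  # pooling is parameter-free; cache it
    val_m = np.stack([prepared[sid][1] for sid in val_ids])
    val_y = np.array([LABEL_TO_INDEX[dataset.oracle_label(sid)] for sid in val_ids])

    history = LossHistory()
    query_log = [
        QueryEvent(0, "initial", sorted(pool.labeled), [float("nan")] * len(pool.labeled))
    ]
    curve_rows = []
    best_post, stale = -1.0, 0  # tracked only once the budget is exhausted

    def labeled_samples() -> list[tuple[np.ndarray, np.ndarray, int]]:
        return [
            (prepared[sid][0], prepared[sid][1], LABEL_TO_INDEX[pool.revealed_labels[sid]])
            for sid in sorted(pool.labeled)
        ]

    for epoch in range(1, config.max_epochs + 1):
        loss = train_epoch(
            model, labeled_samples(), optimizer, config.optimizer, rng_train, config.augmentation
        )
        history.record_epoch(loss)
        optimizer.lr = update_learning_rate(
            optimizer.lr, history, config.optimizer, start_epoch=history.query_epochs[-1]
        )

        val_probs = model.predict_proba(val_pooled, val_m)
        # argmax tie (exactly 0.5/0.5) resolves to index 0 = excluded
        val_acc = float((val_probs.argmax(axis=1) == val_y).mean())
        curve_rows.append(
            {
                "epoch": epoch,
                "n_labeled": len(pool.labeled),
                "train_loss": loss,
                "val_accuracy": val_acc,
                "lr": optimizer.lr,
            }
        )

        budget_left = pool.query_count < config.query_budget and len(pool.unlabeled) > 0
        if budget_left:
            fire, tag = should_query(history, epoch, config.scheduler, rng_timing)
            if fire:
                cand_ids = select_candidates(
                    pool.unlabeled, config.policy.candidate_pool_size, rng_candidates
                )
                if config.policy.selection == "entropy":
                    chosen, scores = select_query_samples(
                        model,
                        {sid: prepared[sid] for sid in cand_ids},
                        config.policy.query_batch_size,
                        rng_scoring,
                        config.augmentation,
                    )
                else:  # random selection baseline at the same query times
                    k = min(config.policy.query_batch_size, len(cand_ids))
                    chosen = list(rng_random_sel.choice(sorted(cand_ids), size=k, replace=False))
                    scores = [float("nan")] * k
                for sid in chosen:
                    pool = data_pools.oracle_reveal(pool, sid)
                query_log.append(QueryEvent(epoch, tag, chosen, scores))
                history.record_query(epoch)

        # stopping: budget spent (or pool exhausted) and accuracy stabilized
        exhausted = pool.query_count >= config.query_budget or not pool.unlabeled
        if exhausted:
            if val_acc > best_post:
                best_post, stale = val_acc, 0
            else:
                stale += 1
            if stale >= config.stop_patience:
                break

    return ALResult(
        learning_curve=pd.DataFrame(curve_rows),
        query_log=query_log,
        model=model,
        pool=pool,
        history=history,
        split=split,
    )
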