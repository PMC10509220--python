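"""Hyperparameter sweep: per-parameter linear searches over log-scaled grids
(repeated three times), followed by a learning-rate × weight-decay grid
search.  "Best" means highest mean validation accuracy under a caller-
supplied objective."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable

import pandas as pd

from .model_training import OptimizerConfig

LOG_FACTORS = (1e-2, 1e-1, 1.0, 1e1, 1e2)


def default_linear_grids(base: OptimizerConfig) -> dict[str, list[float]]:
    """Log-scaled grids around the defaults for the continuous rates."""
    return {
        "learning_rate_init": [base.learning_rate_init * f for f in LOG_FACTORS],
        "weight_decay": [base.weight_decay * f for f in LOG_FACTORS],
        "gamma": sorted(min(0.999, base.gamma * f) for f in (0.5, 0.75, 1.0, 1.05, 1.1)),
    }


@dataclass
class SweepSpec:
    """Grids for the linear phase (parameter → values) and the final
    lr × weight-decay grid phase."""

    linear_grids: dict[str, list[float]] = field(default_factory=dict)
    repeats: int = 3
    lr_grid: list[float] = field(default_factory=lambda: [1e-2 * f for f in LOG_FACTORS])
    wd_grid: list[float] = field(default_factory=lambda: [1e-2 * f for f in LOG_FACTORS])

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if any(not grid for grid in self.linear_grids.values()) or not self.lr_grid or not self.wd_grid:
            raise ValueError("grids must be non-empty")


def run_sweep(
    spec: SweepSpec,
    base_config: OptimizerConfig,
    objective: Callable[[OptimizerConfig], float],
) -> tuple[OptimizerConfig, pd.DataFrame]:
    """Run the two-phase sweep; returns (best configuration, results table).

    The linear phase walks each parameter's grid holding the others at their
    current best, keeps the winner, and repeats the full pass ``repeats``
    times; the grid phase then evaluates every (learning-rate, weight-decay)
    pair.  The results table has one row per evaluation.
    """
    current = dataclasses.replace(base_config)
    rows = []

    for sweep_round in range(spec.repeats):
        for param, grid in spec.linear_grids.items():
            best_value, best_score = getattr(current, param), -float("inf")
            for value in grid:
                candidate = dataclasses.replace(current, **{param: value})
                score = objective(candidate)
                rows.append(
                    {"phase": "linear", "round": sweep_round, "parameter": param,
                     "value": value, "score": score}
                )
                if score > best_score:
                    best_value, best_score = value, score
            current = dataclasses.replace(current, **{param: best_value})

    best_pair, best_score = (current.learning_rate_init, current.weight_decay), -float("inf")
    for lr in spec.lr_grid:
        for wd in spec.wd_grid:
            candidate = dataclasses.replace(current, learning_rate_init=lr, weight_decay=wd)
            score = objective(candidate)
            rows.append(
                {"phase": "grid", "round": 0, "parameter": "lr x wd",
                 "value": (lr, wd), "score": score}
            )
            if score > best_score:
                best_pair, best_score = (lr, wd), score
    current = dataclasses.replace(
        current, learning_rate_init=best_pair[0], weight_decay=best_pair[1]
    )
    return current, pd.DataFrame(rows)
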