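"""Validation metrics: accuracy with 95% CI, confusion-derived rates, and
cross-replicate summaries.

*Included* is the positive class.  Single-run binomial quantities (accuracy,
sensitivity, specificity, precision, NPV) carry Wilson score intervals;
across-replicate summaries (best accuracy, epoch at best) carry t-intervals
over seeds.  An exact 0.5/0.5 prediction resolves to *excluded* —
conservative inclusion, and deterministic.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .data_pools import LABEL_TO_INDEX, Label
from .model_training import ClassifierModel


@dataclass(frozen=True)
class RateWithCI:
    value: float
    ci_low: float
    ci_high: float


def _wilson(successes: int, trials: int) -> RateWithCI:
    if trials == 0:
        return RateWithCI(float("nan"), float("nan"), float("nan"))
    point = successes / trials
    lo, hi = proportion_confint(successes, trials, alpha=0.05, method="wilson")
    # guard against tiny numeric excursions outside [0, 1] or past the point
    lo = min(float(np.clip(lo, 0, 1)), point)
    hi = max(float(np.clip(hi, 0, 1)), point)
    return RateWithCI(point, lo, hi)


@dataclass(frozen=True)
class EvalReport:
    """Accuracy (as a percentage, Wilson 95% CI) plus the 2×2 confusion table
    and its derived rates; ``confusion`` rows are truth (excluded, included),
    columns are prediction."""

    accuracy_pct: float
    ci_low_pct: float
    ci_high_pct: float
    sensitivity: RateWithCI
    specificity: RateWithCI
    precision: RateWithCI
    npv: RateWithCI
    n_validation: int
    confusion: tuple[tuple[int, int], tuple[int, int]]
    ci_method: str = "wilson"

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_counts(cls, tp: int, fn: int, tn: int, fp: int) -> "EvalReport":
        n = tp + fn + tn + fp
        acc = _wilson(tp + tn, n)
        return cls(
            accuracy_pct=acc.value * 100,
            ci_low_pct=acc.ci_low * 100,
            ci_high_pct=acc.ci_high * 100,
            sensitivity=_wilson(tp, tp + fn),
            specificity=_wilson(tn, tn + fp),
            precision=_wilson(tp, tp + fp),
            npv=_wilson(tn, tn + fn),
            n_validation=n,
            confusion=((tn, fp), (fn, tp)),
        )


def evaluate(
    model: ClassifierModel,
    images: np.ndarray,
    metadata: np.ndarray,
    truth: list[Label] | np.ndarray,
) -> EvalReport:
    """Score a validation set: argmax prediction per sample (tie → excluded),
    then accuracy and Table-style confusion metrics with Wilson 95% CIs."""
    if len(images) == 0:
        raise ValueError("validation set is empty")
    probs = model.predict_proba(np.asarray(images), np.asarray(metadata))
    pred = probs.argmax(axis=1)  # ties pick index 0 = excluded
    y = np.array([LABEL_TO_INDEX[Label.coerce(t)] if not isinstance(t, (int, np.integer)) else t
                  for t in truth])
    tp = int(((pred == 1) & (y == 1)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    return EvalReport.from_counts(tp, fn, tn, fp)


@dataclass(frozen=True)
class ReplicateSummary:
    """Across-seed summary of replicate runs: per-seed best validation
    accuracy and the epoch it was reached, with t-based 95% CIs (undefined
    for a single replicate)."""

    best_accuracies: list[float]
    best_epochs: list[int]
    mean_accuracy: float
    accuracy_ci: tuple[float, float] | None
    mean_epoch: float
    epoch_ci: tuple[float, float] | None
    ci_method: str = "t"


def _t_interval(values: list[float]) -> tuple[float, float] | None:
    if len(values) < 2:
        return None
    mean = float(np.mean(values))
    sem = float(np.std(values, ddof=1)) / math.sqrt(len(values))
    half = stats.t.ppf(0.975, df=len(values) - 1) * sem
    return (mean - half, mean + half)


def summarize_replicates(curves: list[pd.DataFrame]) -> ReplicateSummary:
    """Extract each run's best validation accuracy (earliest epoch on ties)
    and summarize across replicates.  Permutation-invariant in run order."""
    if not curves:
        raise ValueError("need at least one run")
    best_acc, best_ep = [], []
    for curve in curves:
        i = int(curve["val_accuracy"].idxmax())
        best_acc.append(float(curve.loc[i, "val_accuracy"]))
        best_ep.append(int(curve.loc[i, "epoch"]))
    return ReplicateSummary(
        best_accuracies=best_acc,
        best_epochs=best_ep,
        mean_accuracy=float(np.mean(best_acc)),
        accuracy_ci=_t_interval(best_acc),
        mean_epoch=float(np.mean(best_ep)),
        epoch_ci=_t_interval([float(e) for e in best_ep]),
    )


def accuracy_vs_labels(curve: pd.DataFrame) -> pd.DataFrame:
    """The label-efficiency trade-off: for each labeled-pool size reached
    during a run, the maximum validation accuracy attained at that size."""
    out = (
        curve.groupby("n_labeled", as_index=False)["val_accuracy"]
        .max()
        .rename(columns={"val_accuracy": "max_val_accuracy"})
        .sort_values("n_labeled", ignore_index=True)
    )
    return out
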