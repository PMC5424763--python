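"""Sequential floating forward selection (SFFS) of feature subsets.

Starting from a designated basic feature, SFFS alternates a forward step —
add the feature whose inclusion maximizes the criterion — with conditional
backward steps that remove a feature whenever the reduced subset strictly
beats the best criterion previously seen at that size.  The criterion here
is the validation accuracy of a back-propagation network trained on the
candidate subset, but any deterministic ``subset -> score`` callable works.
The full search trace (one subset and score per accepted step) is recorded;
the best subset is the trace-wide argmax.

The search runs until the step budget is exhausted or the pool is full;
forward steps are taken even when they lower the score (the floating
removals may later recover), which mirrors the non-monotone accuracy
trajectories such searches typically produce.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from seedvision.bpnn import GOOD, NG, TrainConfig, predict_batch, train_classifier


@dataclass
class SFFSStep:
    subset: frozenset
    criterion: float
    action: str  # "init" | "add" | "remove"
    feature: int


@dataclass
class SFFSTrace:
    steps: list[SFFSStep] = field(default_factory=list)

    @property
    def best_step(self) -> SFFSStep:
        return max(self.steps, key=lambda s: s.criterion)

    @property
    def best_subset(self) -> frozenset:
        return self.best_step.subset

    @property
    def best_criterion(self) -> float:
        return self.best_step.criterion

    def to_frame(self) -> pd.DataFrame:
        """Trace as a table: step, accuracy, subset (sorted feature numbers)."""
        return pd.DataFrame(
            {
                "step": range(1, len(self.steps) + 1),
                "accuracy": [s.criterion for s in self.steps],
                "subset": ["{" + ", ".join(map(str, sorted(s.subset))) + "}" for s in self.steps],
            }
        )


def sffs(pool: Iterable[int], basic: int, criterion: Callable[[frozenset], float],
         max_steps: int = 30) -> SFFSTrace:
    """Run SFFS over ``pool`` starting from the ``basic`` feature.

    ``criterion`` maps a frozenset of feature numbers to a score and must be
    deterministic.  Ties in either direction break toward the lowest feature
    number.  Each accepted step differs from its predecessor by exactly one
    feature.
    """
    pool = frozenset(pool)
    if not pool:
        raise ValueError("empty feature pool")
    if basic not in pool:
        raise ValueError(f"basic feature {basic} not in pool")
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")

    cache: dict[frozenset, float] = {}

    def evaluate(subset: frozenset) -> float:
        if subset not in cache:
            cache[subset] = float(criterion(subset))
        return cache[subset]

    current = frozenset([basic])
    trace = SFFSTrace()
    trace.steps.append(SFFSStep(current, evaluate(current), "init", basic))
    best_by_size: dict[int, float] = {1: trace.steps[0].criterion}

    def record(subset: frozenset, value: float, action: str, feat: int) -> None:
        trace.steps.append(SFFSStep(subset, value, action, feat))
        k = len(subset)
        if value > best_by_size.get(k, -np.inf):
            best_by_size[k] = value

    while len(trace.steps) < max_steps and current != pool:
        # forward: add the argmax-gain feature (ties -> lowest number)
        candidates = sorted(pool - current)
        scores = [evaluate(current | {f}) for f in candidates]
        best_i = int(np.argmax(scores))
        f_add, val = candidates[best_i], scores[best_i]
        current = current | {f_add}
        record(current, val, "add", f_add)

        # conditional backward: remove while it strictly improves the best
        # known criterion at the reduced size
        while len(current) > 2 and len(trace.steps) < max_steps:
            rem_candidates = sorted(current)
            rem_scores = [evaluate(current - {f}) for f in rem_candidates]
            best_j = int(np.argmax(rem_scores))
            f_rem, rem_val = rem_candidates[best_j], rem_scores[best_j]
            if rem_val > best_by_size.get(len(current) - 1, -np.inf):
                current = current - {f_rem}
                record(current, rem_val, "remove", f_rem)
            else:
                break
    return trace


def evaluate_subset(subset: Iterable[int], train_table: pd.DataFrame,
                    validation_table: pd.DataFrame, cfg: TrainConfig | None = None,
                    pool_columns: dict[int, str] | None = None,
                    label_column: str = "label") -> float:
    """Validation accuracy of a BPNN trained on the given feature subset.

    ``pool_columns`` maps feature numbers to table columns; by default the
    numbers index the table's non-label columns in order (1-based).  The
    network is sized by the hidden-node rule for ``len(subset)`` inputs and
    trained fully seeded, so repeated calls return identical accuracies.
    """
    subset = sorted(set(subset))
    if not subset:
        raise ValueError("subset must be non-empty")
    if pool_columns is None:
        feature_cols = [c for c in train_table.columns if c != label_column]
        pool_columns = {i + 1: c for i, c in enumerate(feature_cols)}
    cols = [pool_columns[f] for f in subset]
    y_train = list(train_table[label_column])
    for cls in (GOOD, NG):
        if cls not in y_train:
            raise ValueError(f"class {cls!r} absent from the training split")
    cfg = cfg or TrainConfig()
    with np.errstate(over="ignore"):
        import warnings as _warnings
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # non-convergence is fine here
            model = train_classifier(train_table[cols].to_numpy(np.float64), y_train,
                                     cfg, feature_columns=cols)
    pred = predict_batch(model, validation_table[cols].to_numpy(np.float64))
    truth = list(validation_table[label_column])
    return float(np.mean([p == t for p, t in zip(pred, truth)]))


def make_subset_criterion(train_table: pd.DataFrame, validation_table: pd.DataFrame,
                          cfg: TrainConfig | None = None,
                          pool_columns: dict[int, str] | None = None,
                          label_column: str = "label") -> Callable[[frozenset], float]:
    """Bind :func:`evaluate_subset` into an SFFS criterion callable."""
    def criterion(subset: frozenset) -> float:
        return evaluate_subset(subset, train_table, validation_table, cfg,
                               pool_columns, label_column)
    return criterion
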