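"""Budgeted training with plateau-driven learning-rate decay and early stopping.

A model is trained for a fixed budget (steps, or wall-seconds translated to
steps via a timed warm-up step), with the validation balanced accuracy
recorded at a cadence chosen so the budget yields approximately the target
number of validation evaluations.  After each evaluation the learning rate
is halved if the balanced accuracy failed to improve on the running best
for 3 consecutive evaluations (the stagnation counter resets after each
halving), and training stops once it fails to improve for 10 consecutive
evaluations.  "Improve" is judged against the running best accuracy, not
the immediately preceding value.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np

from .data import class_balanced_accuracy
from .errors import CannotFitError, InvalidInputError
from .nn import make_optimizer

LR_PATIENCE = 3  # halve after this many stagnant validation evaluations
STOP_PATIENCE = 10  # stop after this many


@dataclass(frozen=True)
class TraceEntry:
    samples_seen: int
    balanced_accuracy: float
    learning_rate: float


@dataclass
class ValidationTrace:
    entries: list = field(default_factory=list)
    diagnostics: list = field(default_factory=list)

    def append(self, samples_seen: int, balanced_accuracy: float, learning_rate: float):
        if self.entries and samples_seen <= self.entries[-1].samples_seen:
            raise InvalidInputError("samples_seen must be strictly increasing")
        if not 0.0 <= balanced_accuracy <= 1.0:
            raise InvalidInputError("balanced accuracy must lie in [0, 1]")
        if learning_rate <= 0 or (
            self.entries and learning_rate > self.entries[-1].learning_rate
        ):
            raise InvalidInputError("learning rate must be positive and non-increasing")
        self.entries.append(TraceEntry(samples_seen, balanced_accuracy, learning_rate))

    @property
    def accuracies(self) -> list:
        return [e.balanced_accuracy for e in self.entries]

    def __len__(self):
        return len(self.entries)


@dataclass(frozen=True)
class TrainBudget:
    """Training allotment: ``mode`` is "steps" or "wall" (seconds)."""

    mode: str
    amount: float
    target_validation_evals: int = 20

    def __post_init__(self):
        if self.mode not in ("steps", "wall"):
            raise InvalidInputError(f"unknown budget mode {self.mode!r}")
        if self.amount <= 0:
            raise InvalidInputError("budget amount must be positive")
        if self.target_validation_evals < 1:
            raise InvalidInputError("target_validation_evals must be >= 1")


def find_max_batch_size(fits: Callable[[int], bool], cap: int) -> int:
    """Largest batch size passing the memory probe, less a 10% safety margin.

    ``fits`` must be monotone (if it accepts b it accepts every smaller
    size).  Binary search over [1, cap] uses O(log cap) probes; the margin
    is floor(0.9 × capacity) with a floor of 1.
    """
    if cap < 1:
        raise InvalidInputError("cap must be >= 1")
    if not fits(1):
        raise CannotFitError("batch size 1 does not fit")
    if fits(cap):
        best = cap
    else:
        lo, hi = 1, cap  # fits(lo) True, fits(hi) False
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if fits(mid):
                lo = mid
            else:
                hi = mid
        best = lo
    return max(1, math.floor(0.9 * best))


def _improvement_flags(accuracies) -> list:
    """flag[i] = accuracy i strictly exceeded the best seen before it."""
    best = -math.inf
    flags = []
    for a in accuracies:
        flags.append(a > best)
        best = max(best, a)
    return flags


def schedule_lr(trace: ValidationTrace) -> float:
    """Next learning rate after the latest validation evaluation.

    Replays the plateau rule over the whole trace: the rate halves whenever
    3 consecutive evaluations fail to beat the running best, and the
    stagnation counter resets after each halving.
    """
    if len(trace) == 0:
        raise InvalidInputError("trace must be non-empty")
    lr = trace.entries[0].learning_rate
    stagnant = 0
    for improved in _improvement_flags(trace.accuracies):
        stagnant = 0 if improved else stagnant + 1
        if stagnant == LR_PATIENCE:
            lr /= 2.0
            stagnant = 0
    return lr


def should_stop(trace: ValidationTrace) -> bool:
    """True iff the last 10 evaluations all failed to beat the running best."""
    flags = _improvement_flags(trace.accuracies)
    return len(flags) >= STOP_PATIENCE and not any(flags[-STOP_PATIENCE:])


def evaluate_balanced_accuracy(model, batches: Iterable, n_classes: int) -> float:
    """Confusion-matrix balanced accuracy of a model over one-hot batches."""
    conf = np.zeros((n_classes, n_classes))
    for batch in batches:
        pred = model.predict(batch.one_hot)
        for t, p in zip(batch.labels, pred):
            conf[t, p] += 1
    return class_balanced_accuracy(conf)


def train_with_budget(
    model,
    train_batches: Iterable,
    validate: Callable[[object], float],
    budget: TrainBudget,
    optimizer: str = "adam",
    initial_lr: float = 1e-3,
    restore_best: bool = False,
) -> ValidationTrace:
    """Train under a budget, validating at a fixed cadence.

    Parameters
    ----------
    model
        A trainable handle exposing ``fit_step(x, y, optimizer, lr)``.
    train_batches
        An iterable of :class:`~seqarchitect.data.SequenceBatch`.
    validate
        Callable evaluating the model's validation balanced accuracy.
    budget
        Step or wall-time allotment; wall time is converted to steps using
        a timed warm-up step so the cadence stays hardware-independent.
    optimizer
        One of adam / adagrad / rmsprop / sgd.
    initial_lr
        Starting learning rate; subsequent rates follow the plateau rule.
    restore_best
        Restore the parameters from the best validation evaluation when
        training ends (convergence is judged on the validation set, so the
        returned model is the converged one, not the post-plateau state).

    Returns the full validation trace.  A non-finite loss aborts training,
    returning the trace recorded so far with a diagnostic appended.
    """
    opt = make_optimizer(optimizer, model)
    trace = ValidationTrace()
    batches = iter(train_batches)

    if budget.mode == "steps":
        total_steps = int(budget.amount)
    else:
        batch = next(batches)
        t0 = time.perf_counter()
        loss = model.fit_step(batch.one_hot, batch.labels, opt, initial_lr)
        per_step = max(time.perf_counter() - t0, 1e-9)
        total_steps = max(1, int(budget.amount / per_step)) - 1
        if not np.isfinite(loss):
            trace.diagnostics.append("non-finite loss at warm-up step")
            return trace

    cadence = max(1, total_steps // budget.target_validation_evals)
    lr = initial_lr
    samples = 0
    best_acc = -math.inf
    best_params = None
    for step in range(1, total_steps + 1):
        batch = next(batches)
        loss = model.fit_step(batch.one_hot, batch.labels, opt, lr)
        samples += batch.one_hot.shape[0]
        if not np.isfinite(loss):
            trace.diagnostics.append(f"non-finite loss at step {step}")
            break
        if step % cadence == 0:
            acc = validate(model)
            trace.append(samples, acc, lr)
            if restore_best and acc > best_acc:
                best_acc = acc
                best_params = _snapshot_params(model)
            lr = schedule_lr(trace)
            if should_stop(trace):
                break
    if restore_best and best_params is not None:
        _restore_params(model, best_params)
    return trace


def _snapshot_params(model):
    snap = []
    for layer in model.trainable_layers:
        entry = {k: v.copy() for k, v in layer.params.items()}
        if hasattr(layer, "running_mean"):
            entry["__rm"] = layer.running_mean.copy()
            entry["__rv"] = layer.running_var.copy()
        snap.append(entry)
    return snap


def _restore_params(model, snapshot):
    for layer, params in zip(model.trainable_layers, snapshot):
        for k, v in params.items():
            if k == "__rm":
                layer.running_mean = v.copy()
            elif k == "__rv":
                layer.running_var = v.copy()
            else:
                layer.params[k][...] = v
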