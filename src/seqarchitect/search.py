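"""End-to-end architecture search: data in, best configuration out.

Wires the search space, builder, numpy backend, data pipeline and the
multi-fidelity Bayesian optimizer into a single driver.  Fidelities are
expressed as training-step budgets; a two-stage schedule trains each
proposed configuration briefly first, then warm-starts a longer stage with
every short-budget record in the surrogate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .build import build_plan, instantiate
from .data import BatchSampler, class_balanced_accuracy, iterate_test_samples
from .errors import InvalidInputError
from .optimize import extract_objective, run_mbo, warm_start
from .space import HyperparamConfig, SearchSpace, define_search_space
from .train import TrainBudget, train_with_budget


# Range bounds for desk-scale (CPU) searches.  The full-scale space is
# matched to runs of several hundred evaluations; a desk-scale run affords a
# few dozen, so capacity (depth, kernels, filters, units), dilation and
# regularization extremes are narrowed proportionally while the training
# dimensions the optimizer must navigate (optimizer choice, learning rate,
# pooling, skip ratio, reverse complement) keep their full ranges.
DESK_SCALE_OVERRIDES = {
    "n_conv_layers": (1, 3),
    "n_conv_blocks": (1, 3),
    "kernel_size_0": (16, 32),
    "kernel_size_end": (16, 32),
    "filters_0": (4, 32),
    "filters_end": (4, 32),
    "dilation_end": (1.0, 4.0),
    "leaky_relu_alpha": (0.0, 0.3),
    "n_dense_layers": (0, 2),
    "dense_units": (16, 48),
    "dense_dropout": (0.0, 0.6),
}


def test_set_balanced_accuracy(model, datasets, L: int, n_classes: int, batch: int = 256) -> float:
    """Deterministic test-split evaluation: all files, windows from position 0."""
    conf = np.zeros((n_classes, n_classes))
    xs, ys = [], []

    def _flush():
        if not xs:
            return
        pred = model.predict(np.stack(xs))
        for t, p in zip(ys, pred):
            conf[t, p] += 1
        xs.clear()
        ys.clear()

    for ci, window in iterate_test_samples(datasets, L):
        xs.append(window)
        ys.append(ci)
        if len(xs) >= batch:
            _flush()
    _flush()
    return class_balanced_accuracy(conf)


def make_validation_scorer(val_datasets, L: int, n_classes: int, max_windows: int = 768):
    """Deterministic scorer over offset-0 windows of the validation split.

    Evaluating a fixed window set removes subsampling noise from the
    search objective, which matters when the validation split is small.
    When the split holds more than ``max_windows`` windows, an evenly
    strided subset is used so each validation stays cheap; the subset is
    still fixed for the whole search.
    """
    xs, ys = [], []
    for ci, window in iterate_test_samples(val_datasets, L):
        xs.append(window)
        ys.append(ci)
    if len(xs) > max_windows:
        stride = -(-len(xs) // max_windows)
        xs = xs[::stride]
        ys = ys[::stride]
    X = np.stack(xs).astype(np.float32)
    y = np.asarray(ys)

    def score(model) -> float:
        conf = np.zeros((n_classes, n_classes))
        for start in range(0, len(X), 512):
            pred = model.predict(X[start : start + 512])
            for t, p in zip(y[start : start + 512], pred):
                conf[t, p] += 1
        return class_balanced_accuracy(conf)

    return score


def make_training_objective(
    space: SearchSpace,
    train_datasets,
    val_datasets,
    n_classes: int,
    batch_size: int = 30,
    phase_for_fidelity=None,
    target_evals_for_fidelity=None,
    seed: int = 0,
):
    """Objective function for :func:`~seqarchitect.optimize.run_mbo`.

    Builds and trains the configuration's network for ``fidelity`` steps and
    returns the trace objective for the fidelity's phase (max validation
    balanced accuracy in phase 1, outlier-robust second-highest of the last
    20 evaluations in phase 2).
    """
    phase_for_fidelity = phase_for_fidelity or {}
    target_evals_for_fidelity = target_evals_for_fidelity or {}
    counter = {"n": 0}
    validate = make_validation_scorer(val_datasets, space.sequence_length, n_classes)

    def objective(config: HyperparamConfig, fidelity: float) -> float:
        counter["n"] += 1
        run_seed = seed + 1009 * counter["n"]
        plan = build_plan(config, space, n_classes)
        model = instantiate(plan, seed=run_seed, dtype=np.float32)
        sampler = BatchSampler(
            train_datasets, space.sequence_length, batch_size, rng=run_seed
        )
        budget = TrainBudget(
            "steps", fidelity, target_evals_for_fidelity.get(fidelity, 20)
        )
        trace = train_with_budget(
            model,
            iter(sampler),
            validate,
            budget,
            optimizer=config["optimizer"],
            initial_lr=config["learning_rate"],
        )
        return extract_objective(trace, phase_for_fidelity.get(fidelity, 1))

    return objective


@dataclass
class ArchitectSearch:
    """Two-fidelity architecture search with a scikit-learn-style surface.

    Parameters are plain constructor fields; :meth:`fit` consumes per-class
    training/validation datasets and exposes the results as fitted
    attributes (``best_config_``, ``best_objective_``, ``records_``,
    ``states_``).
    """

    sequence_length: int = 150
    model_family: str = "gap"
    residual: bool = False
    overrides: dict | None = None
    n_classes: int = 3
    batch_size: int = 30
    fidelities: tuple = (200, 900)  # training steps per stage
    stage_iterations: tuple = (6, 5)
    q: int = 3
    init_design: int = 8
    target_evals: tuple = (10, 20)
    seed: int = 0

    def get_params(self, deep: bool = True) -> dict:
        return {f: getattr(self, f) for f in self.__dataclass_fields__}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.__dataclass_fields__:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, train_datasets, val_datasets):
        if len(self.fidelities) != 2 or len(self.stage_iterations) != 2:
            raise InvalidInputError("exactly two fidelity stages are supported here")
        t1, t2 = self.fidelities
        space = define_search_space(
            self.sequence_length, self.model_family, self.residual, self.overrides
        )
        objective = make_training_objective(
            space,
            train_datasets,
            val_datasets,
            self.n_classes,
            batch_size=self.batch_size,
            phase_for_fidelity={t1: 1, t2: 2},
            target_evals_for_fidelity={t1: self.target_evals[0], t2: self.target_evals[1]},
            seed=self.seed,
        )
        rng = np.random.default_rng(self.seed)
        state1 = run_mbo(
            objective,
            space,
            iterations=self.stage_iterations[0],
            q=self.q,
            init_design=self.init_design,
            fidelity=t1,
            rng=rng,
        )
        carried = warm_start(state1, t2)
        state2 = run_mbo(
            objective,
            space,
            iterations=self.stage_iterations[1],
            q=self.q,
            fidelity=t2,
            rng=rng,
            warm_records=carried.records,
        )
        self.space_ = space
        self.states_ = (state1, state2)
        self.records_ = list(state2.records)
        best = state2.best_at_fidelity(t2)
        self.best_config_ = best.config
        self.best_objective_ = best.objective
        return self

    def train_best(
        self,
        train_datasets,
        val_datasets,
        budget_steps: int = 2000,
        batch_size: int | None = None,
    ):
        """Retrain the best configuration to convergence under a step cap;
        returns (model, trace).  A larger batch than during the search
        steadies the final fit."""
        if not hasattr(self, "best_config_"):
            raise InvalidInputError("fit must run before train_best")
        batch_size = batch_size or 3 * self.batch_size
        plan = build_plan(self.best_config_, self.space_, self.n_classes)
        model = instantiate(plan, seed=self.seed + 7, dtype=np.float32)
        sampler = BatchSampler(
            train_datasets, self.sequence_length, batch_size, rng=self.seed + 11
        )
        validate = make_validation_scorer(
            val_datasets, self.sequence_length, self.n_classes
        )

        trace = train_with_budget(
            model,
            iter(sampler),
            validate,
            TrainBudget("steps", budget_steps, self.target_evals[1]),
            optimizer=self.best_config_["optimizer"],
            initial_lr=self.best_config_["learning_rate"],
            restore_best=True,
        )
        return model, trace
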