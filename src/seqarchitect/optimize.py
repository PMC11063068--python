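"""Batch-parallel Bayesian optimization over the architecture space.

A Gaussian-process surrogate (Matérn-3/2 kernel) is fit to all evaluated
configurations, encoded on the unit cube with the training-budget fidelity
appended as one extra coordinate.  Each iteration proposes a batch of q
configurations by maximizing the UCB infill criterion mean + λ·sd with λ
drawn independently per proposal from an exponential distribution —
different λ draws make different exploration/exploitation trade-offs, which
is what makes the batch diverse.  Searches restart at higher fidelities
with all lower-fidelity records as warm-start data, so cheap early
evaluations steer the expensive later ones.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from .errors import InsufficientDataError, InvalidInputError
from .space import (
    HyperparamConfig,
    SearchSpace,
    from_unit_vector,
    sample_configs,
    to_unit_vector,
)

logger = logging.getLogger(__name__)

# fidelity is appended to the unit-cube encoding as log2(budget) / FIDELITY_SCALE
FIDELITY_SCALE = 16.0

DEFAULT_Q = 3  # proposals per iteration
CANDIDATE_BUDGET = 1000  # random infill candidates per proposal
REFINE_TOP = 10  # candidates refined coordinate-wise
REFINE_STEPS = (0.05, 0.01)


@dataclass(frozen=True)
class EvaluationRecord:
    """One (configuration, fidelity) evaluation: the surrogate's unit of data."""

    config: HyperparamConfig
    fidelity: float
    objective: float
    trace_summary: dict | None = None

    def __post_init__(self):
        if not 0.0 <= self.objective <= 1.0:
            raise InvalidInputError("objective must lie in [0, 1]")
        if self.fidelity <= 0:
            raise InvalidInputError("fidelity must be positive")


@dataclass
class OptimizationState:
    space: SearchSpace
    records: list = field(default_factory=list)
    current_fidelity: float = 1.0
    proposal_width: int = DEFAULT_Q
    rng: np.random.Generator = field(default_factory=np.random.default_rng)

    def append(self, record: EvaluationRecord):
        if record.fidelity > self.current_fidelity:
            raise InvalidInputError("record fidelity exceeds the state's current fidelity")
        self.records.append(record)

    @property
    def best_record(self) -> EvaluationRecord:
        return max(self.records, key=lambda r: r.objective)

    def best_at_fidelity(self, fidelity: float) -> EvaluationRecord:
        at = [r for r in self.records if r.fidelity == fidelity]
        return max(at, key=lambda r: r.objective)


def _fidelity_coord(fidelity: float) -> float:
    return math.log2(fidelity) / FIDELITY_SCALE


def encode_records(records: Sequence[EvaluationRecord], space: SearchSpace):
    X = np.array(
        [
            np.append(to_unit_vector(space, r.config), _fidelity_coord(r.fidelity))
            for r in records
        ]
    )
    y = np.array([r.objective for r in records])
    return X, y


class Surrogate:
    """GP posterior over the encoded space; predicts (mean, sd)."""

    def __init__(self, gp: GaussianProcessRegressor, space: SearchSpace):
        self._gp = gp
        self.space = space

    def predict(self, X) -> tuple:
        mean, sd = self._gp.predict(np.atleast_2d(X), return_std=True)
        return mean, sd

    def predict_config(self, config: HyperparamConfig, fidelity: float) -> tuple:
        x = np.append(to_unit_vector(self.space, config), _fidelity_coord(fidelity))
        mean, sd = self.predict(x[None, :])
        return float(mean[0]), float(sd[0])


def fit_surrogate(records: Sequence[EvaluationRecord], space: SearchSpace) -> Surrogate:
    """Fit the Matérn-3/2 Gaussian process to all evaluation records."""
    if len(records) < 2:
        raise InsufficientDataError("need at least 2 records to fit the surrogate")
    X, y = encode_records(records, space)
    d = X.shape[1]
    kernel = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
        length_scale=np.full(d, 0.5), length_scale_bounds=(1e-2, 1e2), nu=1.5
    ) + WhiteKernel(1e-4, (1e-8, 1e-1))
    gp = GaussianProcessRegressor(
        kernel=kernel, normalize_y=True, alpha=1e-10, random_state=0
    )
    with warnings.catch_warnings():
        # hitting a length-scale bound is routine with few observations
        warnings.simplefilter("ignore", ConvergenceWarning)
        gp.fit(X, y)
    return Surrogate(gp, space)


def _ucb(surrogate: Surrogate, X, lam: float):
    mean, sd = surrogate.predict(X)
    return mean + lam * sd


def _canonicalize(space: SearchSpace, X: np.ndarray) -> np.ndarray:
    """Snap raw unit-cube points onto encodings a decoded config realizes.

    Integer, boolean and categorical dimensions only take grid values after
    decoding; scoring the infill criterion at off-grid points would
    overstate the surrogate's uncertainty there.  Vectorized equivalent of
    ``to_unit_vector(space, from_unit_vector(space, x))``.
    """
    X = np.clip(np.atleast_2d(np.asarray(X, dtype=float)), 0.0, 1.0).copy()
    pos = 0
    for d in space.defs:
        if d.kind == "categorical":
            k = len(d.range)
            block = X[:, pos : pos + k]
            hot = np.zeros_like(block)
            hot[np.arange(len(X)), block.argmax(axis=1)] = 1.0
            X[:, pos : pos + k] = hot
            pos += k
            continue
        col = X[:, pos]
        if d.kind == "boolean":
            X[:, pos] = (col >= 0.5).astype(float)
        elif d.kind == "integer":
            lo, hi = d.range
            if hi == lo:
                X[:, pos] = 0.0
            else:
                v = np.clip(np.floor(lo + col * (hi - lo) + 0.5), lo, hi)
                X[:, pos] = (v - lo) / (hi - lo)
        else:
            if d.range[0] == d.range[1]:
                X[:, pos] = 0.0
        pos += 1
    return X


def _maximize_ucb(surrogate: Surrogate, fid_coord: float, lam: float, rng) -> np.ndarray:
    """Random search plus coordinate-wise refinement on the unit cube."""
    space = surrogate.space
    d = space.encoding_dim
    cand = _canonicalize(space, rng.uniform(0.0, 1.0, size=(CANDIDATE_BUDGET, d)))
    Xc = np.column_stack([cand, np.full(len(cand), fid_coord)])
    scores = _ucb(surrogate, Xc, lam)
    order = np.argsort(scores)[::-1][:REFINE_TOP]
    best_x, best_s = cand[order[0]].copy(), scores[order[0]]
    for idx in order:
        x = cand[idx].copy()
        s = scores[idx]
        for step in REFINE_STEPS:
            # coordinate sweep, scored in one surrogate call per pass
            for _ in range(2):
                trials = np.repeat(x[None, :], 2 * d, axis=0)
                for dim in range(d):
                    trials[2 * dim, dim] = np.clip(x[dim] - step, 0.0, 1.0)
                    trials[2 * dim + 1, dim] = np.clip(x[dim] + step, 0.0, 1.0)
                trials = _canonicalize(space, trials)
                T = np.column_stack([trials, np.full(len(trials), fid_coord)])
                ts = _ucb(surrogate, T, lam)
                j = int(np.argmax(ts))
                if ts[j] <= s:
                    break
                s = ts[j]
                x = trials[j]
        if s > best_s:
            best_s, best_x = s, x
    return best_x


def propose_batch(
    state: OptimizationState, surrogate: Surrogate, q: int = DEFAULT_Q, rng=None
) -> list:
    """Propose q distinct configurations via UCB with exponential λ draws."""
    if q < 1:
        raise InvalidInputError("q must be >= 1")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    fid_coord = _fidelity_coord(state.current_fidelity)
    proposals: list = []
    attempts = 0
    while len(proposals) < q and attempts < 10 * q:
        lam = float(gen.exponential(1.0))
        x = _maximize_ucb(surrogate, fid_coord, lam, gen)
        cfg = from_unit_vector(state.space, x)
        if cfg not in proposals:
            proposals.append(cfg)
        attempts += 1
    while len(proposals) < q:  # pathological surrogate: fall back to random draws
        cfg = sample_configs(state.space, 1, gen)[0]
        if cfg not in proposals:
            proposals.append(cfg)
    return proposals


def initial_design(space: SearchSpace, n: int, rng) -> list:
    """Space-filling start: per-dimension stratified (latin-hypercube) draws."""
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    d = space.encoding_dim
    strata = (np.arange(n)[:, None] + gen.uniform(size=(n, d))) / n
    for dim in range(d):
        strata[:, dim] = strata[gen.permutation(n), dim]
    return [from_unit_vector(space, strata[i]) for i in range(n)]


def default_init_size(space: SearchSpace) -> int:
    numeric = sum(1 for dd in space.defs if dd.is_numeric)
    return max(8, 4 * numeric)


def run_mbo(
    objective_fn: Callable[[HyperparamConfig, float], float],
    space: SearchSpace,
    iterations: int,
    q: int = DEFAULT_Q,
    init_design: int | None = None,
    fidelity: float = 1.0,
    rng=None,
    warm_records: Sequence[EvaluationRecord] | None = None,
) -> OptimizationState:
    """Run one fidelity stage of the architecture search.

    Evaluates a space-filling initial design (skipped when warm-start
    records supply coverage), then ``iterations`` rounds of q UCB batch
    proposals, each evaluated by ``objective_fn(config, fidelity)``.  A
    failing evaluation is recorded with objective 0 and a logged
    diagnostic; the run continues.
    """
    if iterations < 0:
        raise InvalidInputError("iterations must be >= 0")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    warm = list(warm_records) if warm_records else []
    state = OptimizationState(
        space=space,
        records=warm,
        current_fidelity=float(fidelity),
        proposal_width=q,
        rng=gen,
    )

    def _evaluate(cfg):
        try:
            obj = float(objective_fn(cfg, fidelity))
            if not np.isfinite(obj):
                raise ValueError(f"objective returned non-finite value {obj}")
            obj = min(1.0, max(0.0, obj))
        except Exception as exc:  # noqa: BLE001 — robustness of long searches
            logger.warning("objective evaluation failed (%s); recording 0", exc)
            obj = 0.0
        state.append(EvaluationRecord(config=cfg, fidelity=fidelity, objective=obj))

    if not warm:
        n0 = init_design if init_design is not None else default_init_size(space)
        if n0 < 2:
            raise InvalidInputError("init_design must be >= 2 without warm-start records")
        for cfg in initial_design(space, n0, gen):
            _evaluate(cfg)

    for _ in range(iterations):
        surrogate = fit_surrogate(state.records, space)
        for cfg in propose_batch(state, surrogate, q, gen):
            _evaluate(cfg)
    return state


def warm_start(previous_state: OptimizationState, new_fidelity: float) -> OptimizationState:
    """Carry every record into a fresh state at a strictly higher fidelity."""
    if new_fidelity <= previous_state.current_fidelity:
        raise InvalidInputError(
            f"new fidelity {new_fidelity} must exceed the current "
            f"fidelity {previous_state.current_fidelity}"
        )
    return OptimizationState(
        space=previous_state.space,
        records=list(previous_state.records),
        current_fidelity=float(new_fidelity),
        proposal_width=previous_state.proposal_width,
        rng=previous_state.rng,
    )


def extract_objective(trace, phase: int) -> float:
    """Objective value a finished training run contributes to the surrogate.

    Phase 1 (short budget): the highest validation balanced accuracy seen
    anywhere in the trace.  Phase 2 (long budget): the *second*-highest
    value among the last 20 validation evaluations, which avoids rewarding
    noisy training processes for single outliers; a window with fewer than
    two entries falls back to its maximum.
    """
    accs = list(getattr(trace, "accuracies", trace))
    if not accs:
        raise InvalidInputError("trace must be non-empty")
    if phase == 1:
        return max(accs)
    if phase == 2:
        window = accs[-20:]
        if len(window) < 2:
            return max(window)
        return sorted(window, reverse=True)[1]
    raise InvalidInputError(f"phase must be 1 or 2, got {phase}")


def random_search(
    objective_fn: Callable[[HyperparamConfig, float], float],
    space: SearchSpace,
    n: int,
    fidelity: float = 1.0,
    rng=None,
) -> OptimizationState:
    """Equal-budget baseline: n uniform draws, no surrogate."""
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    state = OptimizationState(space=space, current_fidelity=float(fidelity), rng=gen)
    for cfg in sample_configs(space, n, gen):
        try:
            obj = min(1.0, max(0.0, float(objective_fn(cfg, fidelity))))
        except Exception:  # noqa: BLE001
            obj = 0.0
        state.append(EvaluationRecord(config=cfg, fidelity=fidelity, objective=obj))
    return state
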