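"""Hyperparameter search space for genomic CNN-GAP / CNN-RNN architectures.

The space jointly describes training hyperparameters (learning rate,
optimizer, reverse-complement input) and layout hyperparameters (number of
convolutional layers and blocks, first/last kernel sizes and filter counts,
dilation and pooling totals, the dense stack, and — depending on the model
family — either the GAP skip ratio or the recurrent stack).  Only the first
and last convolutional layers are parameterized directly; intermediate
layers are interpolated by the architecture builder.

The model family (GAP vs. RNN) and the residual flag are *run-level
conditioning constants*: separate optimization runs are launched for each
combination (a fully crossed design), so they are fields of
:class:`SearchSpace` rather than searched dimensions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import InvalidInputError

GAP = "gap"
RNN = "rnn"
FAMILIES = (GAP, RNN)

_KINDS = ("float", "integer", "boolean", "categorical")


@dataclass(frozen=True)
class HyperparamDef:
    """One tunable dimension: its type, range and conditioning.

    ``range`` is an ordered ``(low, high)`` pair for numeric kinds and the
    tuple of admissible values for boolean/categorical kinds.  ``component``
    groups dimensions by the architectural stage they control;
    ``applies_to`` restricts a dimension to one model family.
    """

    name: str
    kind: str
    range: tuple
    log_scale: bool = False
    component: str = "general"
    applies_to: frozenset = frozenset(FAMILIES)

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise InvalidInputError(f"{self.name}: unknown kind {self.kind!r}")
        if self.kind in ("float", "integer"):
            lo, hi = self.range
            if not lo < hi:
                # equal bounds are tolerated as a degenerate (collapsed) range
                if lo != hi:
                    raise InvalidInputError(
                        f"{self.name}: lower bound {lo} must not exceed upper bound {hi}"
                    )
            if self.log_scale and lo <= 0:
                raise InvalidInputError(
                    f"{self.name}: log-scale requires strictly positive bounds"
                )
        else:
            if len(self.range) == 0:
                raise InvalidInputError(f"{self.name}: empty value set")
            if len(set(self.range)) != len(self.range):
                raise InvalidInputError(f"{self.name}: duplicate values in set")

    @property
    def is_numeric(self) -> bool:
        return self.kind in ("float", "integer")

    def transform(self, value: float) -> float:
        """Map a raw numeric value onto the scale sampling is uniform on."""
        return math.log(value) if self.log_scale else float(value)

    def inverse_transform(self, t: float) -> float:
        return math.exp(t) if self.log_scale else float(t)


@dataclass(frozen=True)
class HyperparamConfig:
    """A single point in a search space: a name → value mapping."""

    values: Mapping[str, object]

    def __getitem__(self, name):
        return self.values[name]

    def __contains__(self, name):
        return name in self.values

    def get(self, name, default=None):
        return self.values.get(name, default)

    def to_dict(self) -> dict:
        return dict(self.values)

    def __eq__(self, other):
        if not isinstance(other, HyperparamConfig):
            return NotImplemented
        return dict(self.values) == dict(other.values)

    def __hash__(self):
        return hash(tuple(sorted((k, repr(v)) for k, v in self.values.items())))


@dataclass(frozen=True)
class SearchSpace:
    """The full hyperparameter space conditioned on one run setting."""

    defs: tuple
    sequence_length: int
    model_family: str
    residual: bool

    def __post_init__(self):
        names = [d.name for d in self.defs]
        if len(names) != len(set(names)):
            raise InvalidInputError("duplicate hyperparameter names in space")

    def def_by_name(self, name: str) -> HyperparamDef:
        for d in self.defs:
            if d.name == name:
                return d
        raise KeyError(name)

    @property
    def names(self) -> list:
        return [d.name for d in self.defs]

    @property
    def encoding_dim(self) -> int:
        """Dimension of the unit-cube encoding (one-hot for categoricals)."""
        dim = 0
        for d in self.defs:
            if d.kind == "categorical":
                dim += len(d.range)
            else:
                dim += 1
        return dim


def _length_dependent_cap(sequence_length: int) -> float:
    """Upper bound for the dilation and total-pooling dimensions.

    Short mini-sequences (reads, 150–250 nt) get 2**4; long ones
    (contig scale, 10 000 nt) get 2**7.  The cut is placed at 1000 nt.
    """
    return 2.0 ** 7 if sequence_length >= 1000 else 2.0 ** 4


def _table_defs(sequence_length: int) -> list:
    cap = _length_dependent_cap(sequence_length)
    both = frozenset(FAMILIES)
    return [
        HyperparamDef("learning_rate", "float", (1e-6, 1e-2), True, "general", both),
        HyperparamDef("reverse_complement", "boolean", (False, True), False, "general", both),
        HyperparamDef(
            "optimizer", "categorical", ("adam", "adagrad", "rmsprop", "sgd"), False, "general", both
        ),
        HyperparamDef("n_conv_layers", "integer", (1, 20), False, "conv", both),
        HyperparamDef("n_conv_blocks", "integer", (1, 10), False, "conv", both),
        HyperparamDef("kernel_size_0", "float", (2.0 ** 4, 2.0 ** 11), True, "conv", both),
        HyperparamDef("kernel_size_end", "float", (2.0 ** 4, 2.0 ** 11), True, "conv", both),
        HyperparamDef("filters_0", "float", (2.0, 64.0), True, "conv", both),
        HyperparamDef("filters_end", "float", (2.0, 64.0), True, "conv", both),
        HyperparamDef("dilation_end", "float", (1.0, cap), True, "conv", both),
        HyperparamDef("pool_total", "float", (1.0, cap), True, "conv", both),
        HyperparamDef("batchnorm_momentum", "float", (0.0, 0.99), False, "conv", both),
        HyperparamDef("leaky_relu_alpha", "float", (0.0, 1.0), False, "conv", both),
        HyperparamDef("n_dense_layers", "integer", (0, 5), False, "dense", both),
        HyperparamDef("dense_units", "float", (2.0 ** 4, 2.0 ** 11), True, "dense", both),
        HyperparamDef("dense_dropout", "float", (0.0, 0.99), False, "dense", both),
        HyperparamDef(
            "dense_activation", "categorical", ("relu", "tanh", "sigmoid"), False, "dense", both
        ),
        HyperparamDef("gap_skip_ratio", "float", (0.0, 1.0), False, "gap", frozenset({GAP})),
        HyperparamDef(
            "rnn_type", "categorical", ("lstm", "gru"), False, "rnn", frozenset({RNN})
        ),
        HyperparamDef("n_rnn_layers", "integer", (1, 3), False, "rnn", frozenset({RNN})),
        HyperparamDef(
            "rnn_bidirectional", "boolean", (False, True), False, "rnn", frozenset({RNN})
        ),
        HyperparamDef("rnn_units", "float", (2.0 ** 4, 2.0 ** 11), True, "rnn", frozenset({RNN})),
    ]


def define_search_space(
    sequence_length: int,
    model_family: str = GAP,
    residual: bool = False,
    overrides: Mapping[str, tuple] | None = None,
) -> SearchSpace:
    """Build the reference search space for one run setting.

    Parameters
    ----------
    sequence_length
        Length L of the mini-sequences fed to the models, in nucleotides.
        Must be at least 16 so the smallest admissible kernel fits.
    model_family
        ``"gap"`` (CNN-GAP) or ``"rnn"`` (CNN-RNN).
    residual
        Whether convolutional blocks carry residual shortcuts.
    overrides
        Optional per-dimension range overrides, name → ``(low, high)`` for
        numeric kinds or a value tuple for categorical/boolean kinds.  Used
        to narrow the space for small-scale runs.
    """
    if model_family not in FAMILIES:
        raise InvalidInputError(f"unknown model family {model_family!r}")
    if sequence_length < 16:
        raise InvalidInputError(
            f"sequence_length must be >= 16 (got {sequence_length}): the smallest "
            "first-layer kernel would not fit"
        )
    defs = [d for d in _table_defs(sequence_length) if model_family in d.applies_to]
    if overrides:
        by_name = {d.name: d for d in defs}
        for name, rng in overrides.items():
            if name not in by_name:
                raise InvalidInputError(f"override for unknown/inapplicable dimension {name!r}")
            defs[defs.index(by_name[name])] = replace(by_name[name], range=tuple(rng))
    return SearchSpace(
        defs=tuple(defs),
        sequence_length=int(sequence_length),
        model_family=model_family,
        residual=bool(residual),
    )


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def sample_configs(space: SearchSpace, n: int, rng=None) -> list:
    """Draw ``n`` configurations uniformly (log-uniformly where flagged)."""
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    gen = _as_rng(rng)
    out = []
    for _ in range(n):
        values = {}
        for d in space.defs:
            if d.kind == "float":
                if d.range[0] == d.range[1]:
                    values[d.name] = d.range[0]
                else:
                    lo, hi = d.transform(d.range[0]), d.transform(d.range[1])
                    v = d.inverse_transform(gen.uniform(lo, hi))
                    values[d.name] = min(max(v, d.range[0]), d.range[1])
            elif d.kind == "integer":
                lo, hi = d.range
                values[d.name] = int(gen.integers(lo, hi + 1))
            elif d.kind == "boolean":
                values[d.name] = bool(d.range[int(gen.integers(0, len(d.range)))])
            else:
                values[d.name] = d.range[int(gen.integers(0, len(d.range)))]
        out.append(HyperparamConfig(values))
    return out


def to_unit_vector(space: SearchSpace, config: HyperparamConfig) -> np.ndarray:
    """Encode a configuration as a point in [0, 1]^d.

    Numeric dimensions are mapped affinely on their (log-transformed where
    flagged) scale; booleans to {0, 1}; categoricals to one-hot blocks.
    """
    diags = validate_config(space, config)
    if diags:
        raise InvalidInputError("; ".join(diags))
    coords = []
    for d in space.defs:
        v = config[d.name]
        if d.is_numeric:
            lo, hi = d.transform(d.range[0]), d.transform(d.range[1])
            coords.append(0.0 if hi == lo else (d.transform(v) - lo) / (hi - lo))
        elif d.kind == "boolean":
            coords.append(float(bool(v)))
        else:
            block = [0.0] * len(d.range)
            block[d.range.index(v)] = 1.0
            coords.extend(block)
    return np.asarray(coords, dtype=float)


def from_unit_vector(space: SearchSpace, vector: Sequence[float]) -> HyperparamConfig:
    """Decode a unit-cube point into a valid configuration.

    Integers are rounded after the inverse transform; one-hot ties resolve
    to the first listed category.
    """
    vec = np.asarray(vector, dtype=float)
    if vec.shape != (space.encoding_dim,):
        raise InvalidInputError(
            f"expected vector of dimension {space.encoding_dim}, got shape {vec.shape}"
        )
    values = {}
    pos = 0
    for d in space.defs:
        if d.kind == "categorical":
            k = len(d.range)
            block = vec[pos : pos + k]
            values[d.name] = d.range[int(np.argmax(block))]
            pos += k
            continue
        t = float(np.clip(vec[pos], 0.0, 1.0))
        pos += 1
        if d.kind == "boolean":
            values[d.name] = bool(t >= 0.5)
        elif d.kind == "integer":
            lo, hi = d.range
            values[d.name] = int(np.clip(int(math.floor(lo + t * (hi - lo) + 0.5)), lo, hi))
        else:
            if d.range[0] == d.range[1]:
                values[d.name] = d.range[0]
            else:
                lo, hi = d.transform(d.range[0]), d.transform(d.range[1])
                v = d.inverse_transform(lo + t * (hi - lo))
                # the inverse transform can overshoot a bound by one ulp
                values[d.name] = min(max(v, d.range[0]), d.range[1])
    return HyperparamConfig(values)


def validate_config(space: SearchSpace, config: HyperparamConfig) -> list:
    """Return one diagnostic string per violated invariant (empty if valid)."""
    diags = []
    names = set(space.names)
    for key in config.values:
        if key not in names:
            diags.append(f"{key}: not applicable for the {space.model_family} family space")
    for d in space.defs:
        if d.name not in config:
            diags.append(f"{d.name}: missing value")
            continue
        v = config[d.name]
        if d.kind == "float":
            if not isinstance(v, (int, float)) or isinstance(v, bool):
                diags.append(f"{d.name}: expected a number, got {type(v).__name__}")
            elif not (d.range[0] <= v <= d.range[1]):
                diags.append(f"{d.name}: value {v} outside range [{d.range[0]}, {d.range[1]}]")
        elif d.kind == "integer":
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                diags.append(f"{d.name}: expected an integer, got {type(v).__name__}")
            elif not (d.range[0] <= v <= d.range[1]):
                diags.append(f"{d.name}: value {v} outside range [{d.range[0]}, {d.range[1]}]")
        elif d.kind == "boolean":
            if not isinstance(v, (bool, np.bool_)):
                diags.append(f"{d.name}: expected a boolean, got {type(v).__name__}")
        else:
            if v not in d.range:
                diags.append(f"{d.name}: value {v!r} not among {list(d.range)}")
    return diags
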