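"""Deterministic expansion of a hyperparameter configuration into a network plan.

A plan follows the three-stage template shared by successful genomic
sequence classifiers: (i) a trunk of stacked (optionally residual, optionally
dilated) convolutional blocks with interspersed max-pooling, (ii) an
embedding stage — global average pooling over the trailing blocks (CNN-GAP)
or a recurrent stack (CNN-RNN) — and (iii) a fully connected head ending in
normalized class scores.

Only the first and last convolutional layers are parameterized; filter
counts and kernel sizes of intermediate layers are interpolated
exponentially between them, and dilation factors grow exponentially within
each block.  All interpolation uses ceiling to materialize integer layer
settings from the continuous hyperparameters.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, field

from .errors import BuildError, InvalidInputError
from .space import GAP, RNN, HyperparamConfig, SearchSpace, validate_config


def _round_half_away(x: float) -> int:
    """round() with halves away from zero (spreadsheet convention)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class BlockStructure:
    """Realized trunk layout: blocks × layers-per-block."""

    n_blocks: int
    layers_per_block: int

    @property
    def n_layers(self) -> int:
        return self.n_blocks * self.layers_per_block


@dataclass(frozen=True)
class ConvLayerSpec:
    filters: int
    kernel: int
    dilation: int
    batchnorm_momentum: float
    leaky_alpha: float


@dataclass(frozen=True)
class ConvBlock:
    layers: tuple
    residual: bool


@dataclass(frozen=True)
class GapHead:
    """Indices of the trunk blocks whose outputs are average-pooled."""

    tap_blocks: tuple


@dataclass(frozen=True)
class RnnHead:
    cell: str  # "lstm" | "gru"
    n_layers: int
    units: int
    bidirectional: bool


@dataclass(frozen=True)
class DenseSpec:
    units: int
    activation: str
    dropout: float


@dataclass(frozen=True)
class ArchitecturePlan:
    input_length: int
    use_reverse_complement: bool
    conv_blocks: tuple
    pool_after: tuple  # one power-of-two factor per conv layer (1 = none)
    head: object  # GapHead | RnnHead
    dense_stack: tuple
    n_classes: int
    alphabet_size: int = 4

    @property
    def conv_layers(self) -> list:
        return [l for b in self.conv_blocks for l in b.layers]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["head"] = {"kind": "gap" if isinstance(self.head, GapHead) else "rnn",
                     **asdict(self.head)}
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


def plan_from_dict(d: dict) -> ArchitecturePlan:
    head = dict(d["head"])
    kind = head.pop("kind")
    if kind == "gap":
        head_obj = GapHead(tap_blocks=tuple(head["tap_blocks"]))
    else:
        head_obj = RnnHead(cell=head["cell"], n_layers=head["n_layers"],
                           units=head["units"], bidirectional=head["bidirectional"])
    blocks = tuple(
        ConvBlock(layers=tuple(ConvLayerSpec(**l) for l in b["layers"]), residual=b["residual"])
        for b in d["conv_blocks"]
    )
    return ArchitecturePlan(
        input_length=d["input_length"],
        use_reverse_complement=d["use_reverse_complement"],
        conv_blocks=blocks,
        pool_after=tuple(d["pool_after"]),
        head=head_obj,
        dense_stack=tuple(DenseSpec(**s) for s in d["dense_stack"]),
        n_classes=d["n_classes"],
        alphabet_size=d.get("alphabet_size", 4),
    )


def resolve_block_structure(n_conv_layers: int, n_conv_blocks: int) -> BlockStructure:
    """Reconcile the requested layer and block counts.

    The block count is taken directly from ``n_conv_blocks`` unless fewer
    layers than blocks were requested, in which case each layer becomes its
    own block.  Layers per block is the rounded ratio, so the realized
    total ``n_blocks * layers_per_block`` only approximates
    ``n_conv_layers``.
    """
    n_blocks = n_conv_layers if n_conv_layers <= n_conv_blocks else n_conv_blocks
    layers_per_block = max(1, _round_half_away(n_conv_layers / n_blocks))
    return BlockStructure(n_blocks=n_blocks, layers_per_block=layers_per_block)


def filters_per_layer(
    filters_0: float, filters_end: float, structure: BlockStructure, res_block: bool
) -> list:
    """Exponentially interpolated filter counts, blockwise-constant when residual.

    f_i = ceil(f0 * (f_end/f0)**j(i)) where j(i) walks block indices (over
    n_blocks - 1) for residual trunks and layer indices (over n_layers - 1)
    otherwise.  A single layer gets ceil(f0); a residual trunk with one
    block keeps every layer at ceil(f0).
    """
    n = structure.n_layers
    if n == 1:
        return [math.ceil(filters_0)]
    ratio = filters_end / filters_0
    out = []
    for i in range(n):
        if res_block:
            if structure.n_blocks == 1:
                j = 0.0
            else:
                j = (i // structure.layers_per_block) / (structure.n_blocks - 1)
        else:
            j = i / (n - 1)
        out.append(math.ceil(filters_0 * ratio ** j))
    return out


def kernels_per_layer(kernel_0: float, kernel_end: float, n_layers: int) -> list:
    """Exponentially interpolated kernel widths; ceil(k0) for a single layer."""
    if n_layers == 1:
        return [math.ceil(kernel_0)]
    ratio = kernel_end / kernel_0
    return [math.ceil(kernel_0 * ratio ** (i / (n_layers - 1))) for i in range(n_layers)]


def dilations_per_layer(dilation_end: float, structure: BlockStructure) -> list:
    """Dilation grows exponentially from 1 to d_end within each block.

    Layer position q within its block gets ceil(d_end ** (q/(s-1))) for
    block size s; single-layer blocks use dilation 1 (the growth starts at
    1 and has nowhere to go).
    """
    s = structure.layers_per_block
    out = []
    for i in range(structure.n_layers):
        q = i % s
        if s == 1:
            out.append(1)
        else:
            out.append(math.ceil(dilation_end ** (q / (s - 1))))
    return out


def plan_pooling(pool_total: float, n_layers: int) -> list:
    """Distribute the total pooling budget over the gaps after each layer.

    The budget is 2**round(log2 pool_total) halvings; exponents are spread
    as evenly as possible over the n_layers potential pooling sites, with
    the remainder assigned to the latest sites so early layers keep full
    resolution.  Each returned factor is a power of two (1 = no pooling).
    """
    if pool_total < 1:
        raise InvalidInputError("pool_total must be >= 1")
    exponent = _round_half_away(math.log2(pool_total))
    base, rem = divmod(exponent, n_layers)
    factors = []
    for i in range(n_layers):
        e = base + (1 if i >= n_layers - rem else 0)
        factors.append(2 ** e)
    return factors


def pooled_block_count(skip_ratio: float, n_blocks: int) -> int:
    """Number of trailing blocks whose outputs are tapped for GAP.

    ``max(1, ceil((1 - r_s) * n_blocks))``: the skip ratio r_s is the
    fraction of leading blocks whose outputs are skipped, and at least one
    block is always pooled.
    """
    if n_blocks < 1:
        raise InvalidInputError("n_blocks must be >= 1")
    return min(n_blocks, max(1, math.ceil((1.0 - skip_ratio) * n_blocks)))


def build_plan(
    config: HyperparamConfig, space: SearchSpace, n_classes: int
) -> ArchitecturePlan:
    """Assemble the full three-stage plan for one configuration.

    Deterministic: equal configurations yield identical plans.  Raises
    :class:`BuildError` if some layer's dilated receptive extent
    (dilation * (kernel - 1) + 1) exceeds the sequence length remaining at
    that depth after the preceding pooling.
    """
    diags = validate_config(space, config)
    if diags:
        raise InvalidInputError("invalid config: " + "; ".join(diags))
    if n_classes < 2:
        raise InvalidInputError("n_classes must be >= 2")

    structure = resolve_block_structure(config["n_conv_layers"], config["n_conv_blocks"])
    filters = filters_per_layer(
        config["filters_0"], config["filters_end"], structure, space.residual
    )
    kernels = kernels_per_layer(
        config["kernel_size_0"], config["kernel_size_end"], structure.n_layers
    )
    dilations = dilations_per_layer(config["dilation_end"], structure)
    pools = plan_pooling(config["pool_total"], structure.n_layers)

    length = space.sequence_length
    for i, (k, d, p) in enumerate(zip(kernels, dilations, pools)):
        extent = d * (k - 1) + 1
        if extent > length:
            raise BuildError(
                f"conv layer {i}: dilated receptive extent {extent} exceeds the "
                f"sequence length {length} remaining at that depth"
            )
        if p > length:
            raise BuildError(
                f"conv layer {i}: pooling factor {p} exceeds remaining length {length}"
            )
        length //= p

    s = structure.layers_per_block
    blocks = []
    for b in range(structure.n_blocks):
        layer_specs = tuple(
            ConvLayerSpec(
                filters=filters[i],
                kernel=kernels[i],
                dilation=dilations[i],
                batchnorm_momentum=config["batchnorm_momentum"],
                leaky_alpha=config["leaky_relu_alpha"],
            )
            for i in range(b * s, (b + 1) * s)
        )
        blocks.append(ConvBlock(layers=layer_specs, residual=space.residual))

    if space.model_family == GAP:
        n_tapped = pooled_block_count(config["gap_skip_ratio"], structure.n_blocks)
        head = GapHead(tap_blocks=tuple(range(structure.n_blocks - n_tapped, structure.n_blocks)))
    else:
        head = RnnHead(
            cell=config["rnn_type"],
            n_layers=config["n_rnn_layers"],
            units=math.ceil(config["rnn_units"]),
            bidirectional=bool(config["rnn_bidirectional"]),
        )

    dense = tuple(
        DenseSpec(
            units=math.ceil(config["dense_units"]),
            activation=config["dense_activation"],
            dropout=config["dense_dropout"],
        )
        for _ in range(config["n_dense_layers"])
    )

    return ArchitecturePlan(
        input_length=space.sequence_length,
        use_reverse_complement=bool(config["reverse_complement"]),
        conv_blocks=tuple(blocks),
        pool_after=tuple(pools),
        head=head,
        dense_stack=dense,
        n_classes=int(n_classes),
    )


@dataclass(frozen=True)
class ParamCount:
    total: int
    by_stage: dict

    def __post_init__(self):
        assert self.total == sum(self.by_stage.values())


def _trunk_output(plan: ArchitecturePlan):
    """(channels, length) of the trunk output, plus per-block output channels."""
    length = plan.input_length
    block_channels = []
    for block in plan.conv_blocks:
        block_channels.append(block.layers[-1].filters)
    for p in plan.pool_after:
        length //= p
    return block_channels, length


def embedding_width(plan: ArchitecturePlan) -> int:
    """Width of the vector fed to the dense stack (one strand)."""
    block_channels, length = _trunk_output(plan)
    if isinstance(plan.head, GapHead):
        return sum(block_channels[b] for b in plan.head.tap_blocks)
    dirs = 2 if plan.head.bidirectional else 1
    return plan.head.units * dirs * length


def count_parameters(plan: ArchitecturePlan) -> ParamCount:
    """Closed-form trainable parameter count, by stage.

    Conv layer: (kernel * in_channels + 1) * filters weights+bias plus
    2 * filters trainable batch-norm scale/shift.  Residual blocks whose
    input and output widths differ add a width-1 projection convolution.
    Recurrent layers follow the standard gate formulas (4 gates LSTM, 3
    GRU, single bias vector), doubled when bidirectional.  Dense layer:
    (in + 1) * units.
    """
    conv = 0
    in_ch = plan.alphabet_size
    for block in plan.conv_blocks:
        block_in = in_ch
        for layer in block.layers:
            conv += (layer.kernel * in_ch + 1) * layer.filters + 2 * layer.filters
            in_ch = layer.filters
        if block.residual and block_in != in_ch:
            conv += (block_in + 1) * in_ch  # 1x1 projection on the skip path

    head = 0
    if isinstance(plan.head, RnnHead):
        gates = 4 if plan.head.cell == "lstm" else 3
        dirs = 2 if plan.head.bidirectional else 1
        u = plan.head.units
        rnn_in = in_ch
        for _ in range(plan.head.n_layers):
            head += dirs * gates * ((rnn_in + u) * u + u)
            rnn_in = u * dirs

    dense = 0
    width = embedding_width(plan) * (2 if plan.use_reverse_complement else 1)
    for spec in plan.dense_stack:
        dense += (width + 1) * spec.units
        width = spec.units
    dense += (width + 1) * plan.n_classes

    by_stage = {"conv": conv, "head": head, "dense": dense}
    return ParamCount(total=sum(by_stage.values()), by_stage=by_stage)


def instantiate(plan: ArchitecturePlan, seed: int | None = 0, dtype=None):
    """Materialize a plan as a trainable model handle (numpy backend).

    ``dtype`` defaults to float64; float32 roughly triples training
    throughput and is what the search driver uses.
    """
    import numpy as np

    from .nn import SequenceModel

    return SequenceModel(plan, seed=seed, dtype=dtype or np.float64)
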