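"""Architecture builder: interpolation formulas, plan assembly, parameter counts.

The interpolation operations are checked against an independent brute-force
evaluation of the closed-form expressions, written here from scratch.
"""

import math

import numpy as np
import pytest

import seqarchitect as sa
from seqarchitect.build import (
    GapHead,
    RnnHead,
    count_parameters,
    embedding_width,
    plan_from_dict,
)
from seqarchitect.errors import BuildError, InvalidInputError
from seqarchitect.space import HyperparamConfig

from conftest import small_space


# --- independent brute-force oracles ---------------------------------------


def oracle_structure(n_c, n_cb):
    N_cb = n_c if n_c <= n_cb else n_cb
    s_cb = math.floor(n_c / N_cb + 0.5)  # round half away from zero
    return N_cb, s_cb, N_cb * s_cb


def oracle_filters(f0, fend, N_cb, s_cb, res):
    N_c = N_cb * s_cb
    if N_c == 1:
        return [math.ceil(f0)]
    out = []
    for i in range(N_c):
        if res:
            j = 0.0 if N_cb == 1 else math.floor(i / s_cb) / (N_cb - 1)
        else:
            j = i / (N_c - 1)
        out.append(math.ceil(f0 * (fend / f0) ** j))
    return out


def oracle_kernels(k0, kend, N_c):
    if N_c == 1:
        return [math.ceil(k0)]
    return [math.ceil(k0 * (kend / k0) ** (i / (N_c - 1))) for i in range(N_c)]


def oracle_dilations(dend, N_cb, s_cb):
    out = []
    for i in range(N_cb * s_cb):
        q = i % s_cb
        out.append(1 if s_cb == 1 else math.ceil(dend ** (q / (s_cb - 1))))
    return out


# --- block structure --------------------------------------------------------


class TestBlockStructure:
    @pytest.mark.parametrize(
        "n_c,n_cb,expected",
        [
            (9, 7, (7, 1, 7)),
            (1, 10, (1, 1, 1)),
            (20, 3, (3, 7, 21)),
            (7, 7, (7, 1, 7)),
            (5, 2, (2, 3, 6)),  # round(2.5) = 3, half away from zero
        ],
    )
    def test_worked_examples(self, n_c, n_cb, expected):
        s = sa.resolve_block_structure(n_c, n_cb)
        assert (s.n_blocks, s.layers_per_block, s.n_layers) == expected

    def test_matches_oracle_over_full_grid(self):
        for n_c in range(1, 21):
            for n_cb in range(1, 11):
                s = sa.resolve_block_structure(n_c, n_cb)
                assert (s.n_blocks, s.layers_per_block, s.n_layers) == oracle_structure(n_c, n_cb)


class TestInterpolations:
    def test_filters_worked_examples(self):
        s = sa.resolve_block_structure(4, 2)
        assert sa.filters_per_layer(4, 32, s, res_block=True) == [4, 4, 32, 32]
        assert sa.filters_per_layer(4, 32, s, res_block=False) == [4, 8, 16, 32]
        one = sa.resolve_block_structure(1, 1)
        assert sa.filters_per_layer(5.3, 60, one, res_block=False) == [6]
        assert sa.filters_per_layer(32, 32, s, res_block=False) == [32] * 4

    def test_kernels_worked_examples(self):
        assert sa.kernels_per_layer(16, 128, 4) == [16, 32, 64, 128]
        assert sa.kernels_per_layer(33, 33, 5) == [33] * 5
        assert sa.kernels_per_layer(17.2, 17.2, 1) == [18]

    def test_dilations_worked_examples(self):
        s = sa.resolve_block_structure(4, 1)  # one block of four layers
        assert sa.dilations_per_layer(8, s) == [1, 2, 4, 8]
        assert sa.dilations_per_layer(1, s) == [1, 1, 1, 1]
        s1 = sa.resolve_block_structure(3, 3)  # single-layer blocks
        assert sa.dilations_per_layer(16, s1) == [1, 1, 1]

    def test_interpolations_match_oracle_on_random_inputs(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n_c = int(rng.integers(1, 21))
            n_cb = int(rng.integers(1, 11))
            f0, fend = np.exp(rng.uniform(np.log(2), np.log(64), 2))
            k0, kend = np.exp(rng.uniform(np.log(16), np.log(2048), 2))
            dend = np.exp(rng.uniform(0, np.log(16)))
            res = bool(rng.integers(0, 2))
            s = sa.resolve_block_structure(n_c, n_cb)
            assert sa.filters_per_layer(f0, fend, s, res) == oracle_filters(
                f0, fend, s.n_blocks, s.layers_per_block, res
            )
            assert sa.kernels_per_layer(k0, kend, s.n_layers) == oracle_kernels(
                k0, kend, s.n_layers
            )
            assert sa.dilations_per_layer(dend, s) == oracle_dilations(
                dend, s.n_blocks, s.layers_per_block
            )

    def test_monotone_interpolation_when_end_exceeds_start(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            s = sa.resolve_block_structure(int(rng.integers(1, 21)), int(rng.integers(1, 11)))
            f0 = float(rng.uniform(2, 32))
            fend = float(rng.uniform(f0, 64))
            for res in (False, True):
                fs = sa.filters_per_layer(f0, fend, s, res)
                assert all(a <= b for a, b in zip(fs, fs[1:]))


class TestPooling:
    @pytest.mark.parametrize(
        "p_end,n,expected",
        [
            (1.0, 3, [1, 1, 1]),
            (16.0, 2, [4, 4]),
            (8.0, 2, [2, 4]),  # remainder goes to the later gap
            (8.0, 5, [1, 1, 2, 2, 2]),
            (2.9, 1, [4]),  # round(log2 2.9) = round(1.54) = 2 halvings at one site
        ],
    )
    def test_distribution_rule(self, p_end, n, expected):
        factors = sa.plan_pooling(p_end, n)
        assert factors == expected

    def test_product_conserves_rounded_total(self):
        rng = np.random.default_rng(3)
        for _ in range(500):
            p_end = float(np.exp(rng.uniform(0, np.log(128))))
            n = int(rng.integers(1, 21))
            factors = sa.plan_pooling(p_end, n)
            assert all(f >= 1 and (f & (f - 1)) == 0 for f in factors)
            assert np.prod(factors) == 2 ** math.floor(math.log2(p_end) + 0.5)


class TestPooledBlockCount:
    @pytest.mark.parametrize(
        "r_s,n_cb,expected",
        [(0.72, 7, 2), (0.0, 5, 5), (1.0, 5, 1), (0.5, 1, 1), (0.9, 10, 1)],
    )
    def test_tap_count(self, r_s, n_cb, expected):
        assert sa.pooled_block_count(r_s, n_cb) == expected

    def test_always_between_one_and_n_blocks(self):
        rng = np.random.default_rng(4)
        for _ in range(300):
            r_s = float(rng.uniform(0, 1))
            n_cb = int(rng.integers(1, 11))
            n = sa.pooled_block_count(r_s, n_cb)
            assert 1 <= n <= n_cb


# --- plan assembly ----------------------------------------------------------


def _base_gap_values(**over):
    vals = dict(
        learning_rate=1e-3,
        reverse_complement=False,
        optimizer="adam",
        n_conv_layers=7,
        n_conv_blocks=7,
        kernel_size_0=16,
        kernel_size_end=32,
        filters_0=8,
        filters_end=16,
        dilation_end=1.0,
        pool_total=4.0,
        batchnorm_momentum=0.9,
        leaky_relu_alpha=0.1,
        n_dense_layers=2,
        dense_units=32.0,
        dense_dropout=0.2,
        dense_activation="tanh",
        gap_skip_ratio=0.72,
    )
    vals.update(over)
    return vals


class TestBuildPlan:
    def test_seven_block_two_tap_two_tanh_dense_layout(self, gap_space):
        plan = sa.build_plan(HyperparamConfig(_base_gap_values()), gap_space, 3)
        assert len(plan.conv_layers) == 7
        assert plan.head == GapHead(tap_blocks=(5, 6))
        assert len(plan.dense_stack) == 2
        assert all(d.activation == "tanh" for d in plan.dense_stack)

    def test_zero_dense_layers_connects_head_to_output(self, gap_space):
        plan = sa.build_plan(
            HyperparamConfig(_base_gap_values(n_dense_layers=0)), gap_space, 3
        )
        assert plan.dense_stack == ()
        counts = count_parameters(plan)
        assert counts.by_stage["dense"] == (embedding_width(plan) + 1) * 3

    def test_equal_configs_yield_byte_identical_serializations(self, gap_space):
        cfg = HyperparamConfig(_base_gap_values())
        p1 = sa.build_plan(cfg, gap_space, 3)
        p2 = sa.build_plan(HyperparamConfig(dict(cfg.values)), gap_space, 3)
        assert p1.to_json() == p2.to_json()

    def test_serialization_round_trips(self, small_rnn_space):
        cfg = sa.sample_configs(small_rnn_space, 1, rng=9)[0]
        plan = sa.build_plan(cfg, small_rnn_space, 4)
        assert plan_from_dict(plan.to_dict()) == plan

    def test_receptive_extent_violation_names_the_layer(self, gap_space):
        vals = _base_gap_values(kernel_size_0=200, kernel_size_end=200, n_conv_layers=1,
                                n_conv_blocks=1)
        with pytest.raises(BuildError, match="conv layer 0"):
            sa.build_plan(HyperparamConfig(vals), gap_space, 3)

    def test_invalid_config_is_rejected(self, gap_space):
        vals = _base_gap_values(n_conv_layers=25)
        with pytest.raises(InvalidInputError, match="n_conv_layers"):
            sa.build_plan(HyperparamConfig(vals), gap_space, 3)

    @pytest.mark.parametrize("L", [150, 250, 10_000])
    @pytest.mark.parametrize("family", ["gap", "rnn"])
    @pytest.mark.parametrize("residual", [False, True])
    def test_all_sampled_configs_build_or_raise_documented_error(self, L, family, residual):
        space = sa.define_search_space(L, family, residual)
        built = 0
        seed = L + 31 * (family == "rnn") + 63 * residual
        for cfg in sa.sample_configs(space, 1000, rng=seed):
            try:
                plan = sa.build_plan(cfg, space, 3)
            except BuildError:
                continue
            built += 1
            _assert_plan_invariants(plan, cfg, space)
        assert built > 0


def _assert_plan_invariants(plan, cfg, space):
    # residual blocks keep a constant filter count
    for block in plan.conv_blocks:
        if block.residual:
            assert len({l.filters for l in block.layers}) == 1
    # pooling conservation
    assert np.prod(plan.pool_after) == 2 ** math.floor(math.log2(cfg["pool_total"]) + 0.5)
    # GAP taps are a non-empty suffix
    if isinstance(plan.head, GapHead):
        taps = plan.head.tap_blocks
        assert taps and taps[-1] == len(plan.conv_blocks) - 1
        assert list(taps) == list(range(taps[0], len(plan.conv_blocks)))
    # receptive extent fits at every depth
    length = plan.input_length
    for layer, p in zip(plan.conv_layers, plan.pool_after):
        assert layer.dilation * (layer.kernel - 1) + 1 <= length
        length //= p
    assert length >= 1


# --- parameter counting -----------------------------------------------------


class TestCountParameters:
    def test_single_conv_layer_hand_count(self):
        space = small_space("gap")
        vals = _base_gap_values(
            n_conv_layers=1, n_conv_blocks=1, kernel_size_0=16, kernel_size_end=16,
            filters_0=8, filters_end=8, pool_total=1.0, n_dense_layers=0,
            gap_skip_ratio=0.0,
        )
        plan = sa.build_plan(HyperparamConfig(vals), space, 3)
        counts = count_parameters(plan)
        # (16 kernel x 4 channels + 1 bias) x 8 filters + 2 x 8 batch-norm
        assert counts.by_stage["conv"] == (16 * 4 + 1) * 8 + 16 == 536
        assert counts.by_stage["dense"] == (8 + 1) * 3
        assert counts.total == sum(counts.by_stage.values())

    @pytest.mark.parametrize("family", ["gap", "rnn"])
    @pytest.mark.parametrize("residual", [False, True])
    def test_count_matches_backend_trainable_parameters(self, family, residual):
        space = small_space(family, residual)
        checked = 0
        rng_seed = 100
        while checked < 13:  # ~50 plans across the 4 parametrizations
            cfgs = sa.sample_configs(space, 1, rng=rng_seed)
            rng_seed += 1
            try:
                plan = sa.build_plan(cfgs[0], space, 3)
            except BuildError:
                continue
            model = sa.instantiate(plan, seed=0)
            assert model.trainable_count == count_parameters(plan).total
            checked += 1

    def test_reverse_complement_changes_only_first_dense_input(self):
        space = small_space("gap")
        base = _base_gap_values(n_conv_layers=2, n_conv_blocks=2, pool_total=1.0,
                                kernel_size_0=16, kernel_size_end=16, gap_skip_ratio=0.0)
        p_single = sa.build_plan(HyperparamConfig(base), space, 3)
        p_double = sa.build_plan(
            HyperparamConfig({**base, "reverse_complement": True}), space, 3
        )
        delta = count_parameters(p_double).total - count_parameters(p_single).total
        assert delta == embedding_width(p_single) * p_single.dense_stack[0].units
        assert sa.instantiate(p_double, 0).trainable_count == count_parameters(p_double).total
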