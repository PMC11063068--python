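import numpy as np
import pytest

import seqarchitect as sa


@pytest.fixture(scope="session")
def tiny_bundle(tmp_path_factory):
    """Session-wide tiny planted-motif genome collection."""
    out = tmp_path_factory.mktemp("fixtures")
    return sa.fixture_suite("tiny", out, seed=13)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """Session-wide small planted-motif collection (search smoke tests)."""
    out = tmp_path_factory.mktemp("fixtures_small")
    return sa.fixture_suite("small", out, seed=13)


@pytest.fixture
def gap_space():
    return sa.define_search_space(150, "gap", residual=False)


@pytest.fixture
def rnn_space():
    return sa.define_search_space(150, "rnn", residual=False)


# Bounded ranges used where a full-range architecture would be needlessly
# large to instantiate in a unit test.
SMALL_OVERRIDES = {
    "n_conv_layers": (1, 4),
    "n_conv_blocks": (1, 3),
    "kernel_size_0": (16, 64),
    "kernel_size_end": (16, 64),
    "filters_0": (4, 32),
    "filters_end": (4, 32),
    "dense_units": (16, 64),
}

SMALL_RNN_OVERRIDES = dict(SMALL_OVERRIDES, rnn_units=(16, 32))


def small_space(family="gap", residual=False, L=150):
    ov = SMALL_RNN_OVERRIDES if family == "rnn" else SMALL_OVERRIDES
    return sa.define_search_space(L, family, residual, overrides=ov)


@pytest.fixture
def small_gap_space():
    return small_space("gap")


@pytest.fixture
def small_rnn_space():
    return small_space("rnn")
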