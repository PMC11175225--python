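import logging

import numpy as np
import pytest

from rdagan.generator import GeneratorSpec, RDAGANGenerator

logging.getLogger("rdagan").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_spec():
    """A small generator spec for fast structural tests."""
    return GeneratorSpec(num_blocks=2, convs_per_block=3, growth_rate=8,
                         base_channels=16, cbam_reduction=4,
                         head_kernel_size=3, second_shallow_conv=False)


@pytest.fixture
def tiny_generator(tiny_spec):
    return RDAGANGenerator(tiny_spec, np.random.default_rng(7))


def zero_parameters(module):
    """Zero every trainable parameter of a module (residual-identity setup)."""
    for p in module.parameters():
        p.data[...] = 0.0
    return module
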