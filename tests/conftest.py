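import numpy as np
import pytest

from wingspot import StackParams, generate_wing_stack


@pytest.fixture(scope="session")
def clone_stack():
    """One synthetic stack with three single-cell mwh clones and a vein."""
    params = StackParams(
        seed=11, n_mwh_clones=3, clone_size_cells=1, vein_stripes=((40.0, 45.0),)
    )
    stack, truth = generate_wing_stack(params)
    return stack, truth


@pytest.fixture(scope="session")
def plain_stack():
    """A small clone-free stack for filter/segmentation tests."""
    params = StackParams(seed=5, field_size_um=(120.0, 120.0))
    stack, truth = generate_wing_stack(params)
    return stack, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
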