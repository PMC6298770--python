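import numpy as np
import pytest

from tmrpipe import phantom


@pytest.fixture(scope="session")
def small_space():
    """12^3 phantom used by most unit tests."""
    return phantom.make_phantom_space((12, 12, 12), seed=5)


@pytest.fixture(scope="session")
def default_space():
    """Default 20^3 phantom."""
    return phantom.make_phantom_space(seed=0)


@pytest.fixture(scope="session")
def small_templates(small_space):
    return phantom.make_category_templates(small_space, seed=1)


@pytest.fixture(scope="session")
def default_templates(default_space):
    return phantom.make_category_templates(default_space, seed=1)
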