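import numpy as np
import pytest

import rootflux as rf
from rootflux.geometry import TemplateSpec, build_template_from_rectangles


def rect(x0, x1, y0, y1):
    return np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]], float)


@pytest.fixture(scope="session")
def full_template():
    """The default geometrically regular root-tip template."""
    return rf.generate_regular_template()


@pytest.fixture(scope="session")
def small_template():
    """A shorter root tip (400 um) for cheaper dynamic tests."""
    return rf.generate_regular_template(TemplateSpec(ez_length=190.0))


@pytest.fixture(scope="session")
def full_distribution(full_template):
    return rf.build_distribution(full_template)


@pytest.fixture(scope="session")
def small_distribution(small_template):
    return rf.build_distribution(small_template)


@pytest.fixture
def two_cell_template():
    """Two 10x10 cells side by side: 1 shared wall + 6 boundary walls."""
    return build_template_from_rectangles(
        [("cortex", rect(0, 10, 0, 10)), ("cortex", rect(10, 20, 0, 10))]
    )
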