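import numpy as np
import pytest

from fcparc import build_mesh, make_group_template


@pytest.fixture(scope="session")
def mesh2():
    """Level-2 icosphere (162 vertices, 40-vertex ROI cap)."""
    return build_mesh(2)


@pytest.fixture(scope="session")
def template4(mesh2):
    return make_group_template(mesh2, 4, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def orthogonal_courses(n, t=120):
    """n zero-mean, mutually orthogonal unit-variance time courses."""
    time = np.arange(t)
    x = np.array([np.cos(2 * np.pi * (i + 1) * time / t) for i in range(n)])
    x = x - x.mean(axis=1, keepdims=True)
    return x / x.std(axis=1, keepdims=True)
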