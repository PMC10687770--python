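import numpy as np
import pytest

from facecoord.mesh_regions import (
    GlobalExpressionBasis,
    assign_regions,
    build_localized_basis,
)
from facecoord.synthetic_data import gen_mesh


@pytest.fixture(scope="session")
def mesh():
    return gen_mesh(n_points=200, seed=7)


@pytest.fixture(scope="session")
def partition(mesh):
    return assign_regions(mesh)


@pytest.fixture(scope="session")
def global_basis(mesh):
    rng = np.random.default_rng(11)
    return GlobalExpressionBasis(rng.normal(size=(3 * mesh.n_points, 60)))


@pytest.fixture(scope="session")
def localized_basis(global_basis, partition):
    return build_localized_basis(global_basis, partition)
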