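import numpy as np
import pytest

from vertisource.headmodel import (
    assign_rois,
    build_montage,
    build_source_grid,
    compute_leadfield,
    default_roi_spec,
)
from vertisource.inverse import compute_inverse_operator

# Reduced geometry shared across tests: 16-mm grid (~380 voxels) keeps
# every inverse-based test fast while preserving all model properties.
REDUCED_SPACING = 16.0
REDUCED_ROI_RADIUS = 20.0


@pytest.fixture(scope="session")
def montage():
    return build_montage()


@pytest.fixture(scope="session")
def small_grid():
    return build_source_grid(spacing=REDUCED_SPACING)


@pytest.fixture(scope="session")
def small_leadfield(montage, small_grid):
    return compute_leadfield(montage, small_grid)


@pytest.fixture(scope="session")
def small_inverse(small_leadfield):
    return compute_inverse_operator(small_leadfield)


@pytest.fixture(scope="session")
def small_atlas(small_grid):
    return assign_rois(small_grid, default_roi_spec(radius=REDUCED_ROI_RADIUS))


@pytest.fixture()
def rng():
    return np.random.default_rng(20160418)
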