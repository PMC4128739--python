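import numpy as np
import pytest

from patchlink.grids import FUNCTIONAL_LEGEND, GridLandscape
from patchlink.synthetic import (
    MANAGED_TYPOLOGY_SPLIT,
    NATURAL_TYPOLOGY_SPLIT,
    attach_structural_layer,
    generate_functional_landscape,
    managed_spec,
    natural_spec,
)


def functional_landscape(grid, cell=10.0, origin=(0.0, 0.0)):
    """Small helper to build a functional landscape from a literal array."""
    return GridLandscape(
        class_grid=np.asarray(grid),
        cell_size_m=cell,
        legend=dict(FUNCTIONAL_LEGEND),
        level="functional",
        origin_xy=origin,
    )


@pytest.fixture(scope="session")
def natural_small():
    """One clumped natural-composition landscape, 2.5 x 2.5 km."""
    return generate_functional_landscape(natural_spec(dims=(250, 250)), seed=42)


@pytest.fixture(scope="session")
def managed_small():
    """One interspersed managed-composition landscape, 2.5 x 2.5 km."""
    return generate_functional_landscape(managed_spec(dims=(250, 250)), seed=43)


@pytest.fixture(scope="session")
def natural_structural(natural_small):
    return attach_structural_layer(natural_small, NATURAL_TYPOLOGY_SPLIT, seed=7)


@pytest.fixture(scope="session")
def managed_structural(managed_small):
    return attach_structural_layer(managed_small, MANAGED_TYPOLOGY_SPLIT, seed=8)
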