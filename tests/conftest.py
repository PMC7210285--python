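"""Shared fixtures: analytic model densities sampled onto grids.

Heavy objects (field bundles, basin partitions) are session-scoped so the
whole suite builds each grid pipeline once.
"""

import numpy as np
import pytest

from vsf.bader_basins import yt_weights
from vsf.field_calculus import derivatives_fd, field_bundle_from_model
from vsf.model_densities import (GaussianAtom, GaussianDensity,
                                 make_vdw_dimer_fixture,
                                 symmetric_fixture_grid)
from vsf.source_function import SourceFunctionEvaluator


@pytest.fixture(scope="session")
def single_gaussian():
    """Unit-electron spherical Gaussian (alpha = 1) at the origin."""
    return GaussianDensity([GaussianAtom(np.zeros(3), 1.0, 1.0)])


@pytest.fixture(scope="session")
def dimer():
    """Symmetric vdW-like Gaussian dimer: separation 6 bohr, alpha 1."""
    return make_vdw_dimer_fixture(6.0, 1.0)


@pytest.fixture(scope="session")
def dimer_grid_coarse(dimer):
    """Dimer density on a 0.25-bohr symmetric lattice (61 x 37 x 37)."""
    _, model = dimer
    return symmetric_fixture_grid(model, spacing=0.25)


@pytest.fixture(scope="session")
def dimer_grid_fine(dimer):
    """Dimer density on a 0.1875-bohr symmetric lattice (81 x 49 x 49)."""
    _, model = dimer
    return symmetric_fixture_grid(model, spacing=0.1875)


@pytest.fixture(scope="session")
def dimer_bundle_coarse(dimer_grid_coarse):
    return derivatives_fd(dimer_grid_coarse)


@pytest.fixture(scope="session")
def dimer_bundle_fine(dimer_grid_fine):
    return derivatives_fd(dimer_grid_fine)


@pytest.fixture(scope="session")
def dimer_bundle_analytic(dimer, dimer_grid_coarse):
    _, model = dimer
    return field_bundle_from_model(model, dimer_grid_coarse)


@pytest.fixture(scope="session")
def dimer_partition_coarse(dimer, dimer_grid_coarse):
    geom, _ = dimer
    return yt_weights(dimer_grid_coarse, geometry=geom)


@pytest.fixture(scope="session")
def dimer_partition_fine(dimer, dimer_grid_fine):
    geom, _ = dimer
    return yt_weights(dimer_grid_fine, geometry=geom)


@pytest.fixture(scope="session")
def dimer_evaluator_coarse(dimer_partition_coarse, dimer_bundle_coarse,
                           dimer_grid_coarse):
    lap = dimer_grid_coarse.like(dimer_bundle_coarse.laplacian)
    return SourceFunctionEvaluator(dimer_partition_coarse, lap)


@pytest.fixture(scope="session")
def dimer_evaluator_fine(dimer_partition_fine, dimer_bundle_fine,
                         dimer_grid_fine):
    lap = dimer_grid_fine.like(dimer_bundle_fine.laplacian)
    return SourceFunctionEvaluator(dimer_partition_fine, lap)
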