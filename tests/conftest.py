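"""Shared fixtures: meshes, a small synthetic population, and its atlas.

Everything is generated programmatically; session scope keeps the expensive
artifacts (CPC grids, population atlases) shared across test modules.
"""

import numpy as np
import pytest

from tbamontage import (PopulationConfig, ROISpec, build_atlas_from_population,
                        build_cpc_grid, gia_hat_map, make_population,
                        template_scalp, uv_hemisphere)


@pytest.fixture(scope="session")
def unit_sphere():
    """Unit-radius hemispherical scalp with fiducials on the equator."""
    return uv_hemisphere((1.0, 1.0, 1.0), n_az=48, n_rings=24, name="unit")


@pytest.fixture(scope="session")
def sphere90():
    """90 mm spherical scalp (montage-geometry checks)."""
    return uv_hemisphere((90.0, 90.0, 90.0), n_az=40, n_rings=16, name="r90")


@pytest.fixture(scope="session")
def template():
    """Head-sized ellipsoid template scalp (75 x 92 x 80 mm semi-axes)."""
    return uv_hemisphere((75.0, 92.0, 80.0), n_az=40, n_rings=16,
                         name="template")


@pytest.fixture(scope="session")
def grid20(template):
    return build_cpc_grid(template, 20)


@pytest.fixture(scope="session")
def pop_config():
    return PopulationConfig(n=6, seed=42, n_az=40, n_rings=16)


@pytest.fixture(scope="session")
def population(pop_config):
    heads, truth = make_population(pop_config)
    return heads, truth


@pytest.fixture(scope="session")
def pop_template(pop_config):
    return template_scalp(pop_config)


@pytest.fixture(scope="session")
def pop_grid(pop_template):
    return build_cpc_grid(pop_template, 20)


@pytest.fixture(scope="session")
def pop_atlas(population, pop_grid, pop_config):
    heads, _ = population
    return build_atlas_from_population(heads, pop_grid,
                                       vocabulary=pop_config.parcellation)


@pytest.fixture(scope="session")
def pop_roi():
    return ROISpec(roi_labels=("S2",), t=0.5)


@pytest.fixture(scope="session")
def pop_map(pop_atlas, pop_roi):
    return gia_hat_map(pop_atlas, pop_roi)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
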