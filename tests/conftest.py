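"""Shared synthetic-plan fixtures (session-scoped: plans are deterministic)."""

import numpy as np
import pytest

from isdqa import (
    SyntheticPlanSpec,
    make_plan,
    to_percent,
)


@pytest.fixture(scope="session")
def sphere_spec_small():
    # small, fast sphere: linear falloff to zero at 22 mm, 1 mm voxels
    return SyntheticPlanSpec(
        shape="sphere", falloff="linear", radius_mm=22.0, grid_shape=(51, 51, 51)
    )


@pytest.fixture(scope="session")
def sphere_grid_small(sphere_spec_small):
    return make_plan(sphere_spec_small)


@pytest.fixture(scope="session")
def sphere_pct_small(sphere_grid_small):
    return to_percent(sphere_grid_small)


@pytest.fixture(scope="session")
def sphere_spec_r50():
    # linear falloff over 50 mm: r(x) = 50 - x/2, so the +/-1 mm criterion
    # maps to exactly 2 percentage points
    return SyntheticPlanSpec(
        shape="sphere", falloff="linear", radius_mm=50.0,
        grid_shape=(101, 101, 101),
    )


@pytest.fixture(scope="session")
def sphere_grid_r50(sphere_spec_r50):
    return make_plan(sphere_spec_r50)


@pytest.fixture(scope="session")
def sphere_pct_r50(sphere_grid_r50):
    return to_percent(sphere_grid_r50)


@pytest.fixture(scope="session")
def ellipsoid_spec():
    # anisotropic plan with broad distance histograms (clinical analogue)
    return SyntheticPlanSpec(
        shape="ellipsoid", falloff="linear", semi_axes_mm=(50.0, 35.0, 25.0),
        grid_shape=(111, 101, 91),
    )


@pytest.fixture(scope="session")
def ellipsoid_grid(ellipsoid_spec):
    return make_plan(ellipsoid_spec)


@pytest.fixture(scope="session")
def ellipsoid_pct(ellipsoid_grid):
    return to_percent(ellipsoid_grid)


@pytest.fixture(scope="session")
def rotation_base_spec():
    # asymmetric plan whose 50-90 % isodoses are all large surfaces: a
    # sigmoid-falloff ellipsoid (shallow centre, sharp edge)
    return dict(
        shape="ellipsoid", falloff="sigmoid", semi_axes_mm=(48.0, 34.0, 22.0),
        sigmoid_width_mm=4.0, radius_mm=48.0, grid_shape=(121, 111, 101),
    )


@pytest.fixture(scope="session")
def rotation_ref_pct(rotation_base_spec):
    return to_percent(make_plan(SyntheticPlanSpec(**rotation_base_spec)))


@pytest.fixture(scope="session")
def rotation_rotated_pct(rotation_base_spec):
    return to_percent(
        make_plan(SyntheticPlanSpec(**rotation_base_spec, rotation_deg=15.0))
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
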