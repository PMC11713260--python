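"""Shared fixtures: small grids and session-scoped phantom batteries.

Everything is generated programmatically; the only on-disk fixtures are
the bundled cohort summary CSVs inside the package.
"""

from __future__ import annotations

import numpy as np
import pytest

import doseaccum as da
from doseaccum.grid import DoseGrid, Grid, ImageVolume


@pytest.fixture(scope="session")
def default_cfg() -> da.PhantomConfig:
    return da.PhantomConfig()


@pytest.fixture(scope="session")
def default_phantom(default_cfg):
    """Planning CT + structures at the default 96x96x64 geometry."""
    return da.generate_planning_ct(default_cfg)


@pytest.fixture(scope="session")
def default_weekly(default_cfg, default_phantom):
    pct, structs = default_phantom
    return da.generate_weekly_series(pct, structs, default_cfg)


@pytest.fixture(scope="session")
def week1_registration(default_cfg, default_phantom, default_weekly):
    """Rigid + deformable registration of the planning CT to week 1.

    Week 1 carries the largest bladder change of the default battery;
    several geometric and dosimetric checks reuse this registration.
    """
    pct, structs = default_phantom
    weekly, truth = default_weekly
    rigid = da.rigid_register(weekly[0], pct)
    dvf = da.deformable_register(weekly[0], pct, da.RegistrationParams(), init=rigid)
    return rigid, dvf


@pytest.fixture()
def small_grid() -> Grid:
    return Grid((20, 18, 16), (2.0, 2.5, 3.0), (0.0, 0.0, 0.0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_volume(grid: Grid, values, role="image") -> ImageVolume:
    return ImageVolume(grid, np.broadcast_to(values, grid.shape).copy(), role=role)


def make_dose(grid: Grid, values, role="dose") -> DoseGrid:
    return DoseGrid(grid, np.broadcast_to(values, grid.shape).copy(), role=role)


def tiny_phantom_config(**kw):
    """Reduced phantom (48x48x32, small FOV) for fast end-to-end tests."""
    defaults = dict(
        grid_shape=(48, 48, 32),
        spacing_mm=(5.0, 5.0, 4.0),
        body_semi_axes_mm=(105.0, 85.0),
        bladder_center_mm=(0.0, -36.0, 0.0),
        bladder_volume_cc=50.0,
        rectum_center_xy_mm=(0.0, 36.0),
        rectum_radius_mm=10.0,
        rectum_half_length_mm=50.0,
        target_semi_axes_mm=(16.0, 14.0, 22.0),
        bone_outer_semi_axes_mm=(95.0, 78.0),
        bone_half_length_mm=50.0,
        ptv_margin_mm=6.0,
        deform_sigma_mm=35.0,
        cbct_fov_diameter_mm=220.0,
        cbct_fov_longitudinal_mm=120.0,
        weekly_params=(
            da.WeeklyParams(1.3, (2.0, -1.0, 1.0)),
            da.WeeklyParams(0.8, (-1.0, 2.0, 0.0)),
        ),
    )
    defaults.update(kw)
    return da.PhantomConfig(**defaults)


def tiny_pipeline_config(**phantom_kw):
    return da.PipelineConfig(
        phantom=tiny_phantom_config(**phantom_kw),
        registration=da.RegistrationParams(levels=3, iterations=(30, 20, 15)),
    )
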