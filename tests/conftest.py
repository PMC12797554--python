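import dataclasses

import numpy as np
import pandas as pd
import pytest

from chmbiomass.landscape import (
    LandscapeConfig,
    LandscapeTruth,
    generate_landscape,
    sample_nfi_plots,
    true_scope_statistics,
)
from chmbiomass.metrics import add_plot_metrics
from chmbiomass.raster import RasterGrid


def make_uniform_landscape(
    height: float = 10.0,
    extent: float = 400.0,
    cell: float = 2.0,
    biomass: float | None = None,
    n_strata: int = 1,
):
    """Hand-built constant landscape: raster pieces plus exact truth."""
    n = int(extent / cell)
    chm = RasterGrid((0.0, 0.0), cell, np.full((n, n), height))
    codes = np.zeros((n, n), dtype=np.int16)
    stripe = n // n_strata
    for k in range(n_strata):
        codes[k * stripe : (k + 1) * stripe if k < n_strata - 1 else n, :] = 101 + k
    strata = RasterGrid((0.0, 0.0), cell, codes, nodata=-1)
    domains = RasterGrid((0.0, 0.0), cell, np.ones((n, n), dtype=np.int16), nodata=-1)
    bio = biomass if biomass is not None else 3.0 * height**1.4
    truth_grid = RasterGrid((0.0, 0.0), cell, np.full((n, n), float(bio)))
    truth = LandscapeTruth(truth_grid, true_scope_statistics(truth_grid, strata, domains))
    return chm, strata, domains, truth


@pytest.fixture(scope="session")
def demo_config() -> LandscapeConfig:
    return LandscapeConfig(
        extent_m=(1200.0, 1200.0),
        fine_cell_m=2.0,
        stratum_codes=(102, 103, 106),
        n_domains=4,
        mean_height_m=(12.0, 8.0, 15.0),
        height_cv=0.45,
        correlation_range_m=100.0,
        gap_fraction=(0.1, 0.2, 0.05),
        agb_coefficient=3.0,
        agb_exponent=1.4,
        plot_noise_cv=0.25,
        plot_spacing_m=100.0,
        plot_radius_m=25.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def demo_landscape(demo_config):
    return generate_landscape(demo_config)


@pytest.fixture(scope="session")
def demo_plots(demo_landscape, demo_config) -> pd.DataFrame:
    land = demo_landscape
    plots = sample_nfi_plots(
        land.chm, land.strata, land.domains, land.truth,
        spacing_m=demo_config.plot_spacing_m,
        radius_m=demo_config.plot_radius_m,
        cover_min=0.10,
        cover_height_m=4.0,
        noise_cv=demo_config.plot_noise_cv,
        rng=7,
    )
    return add_plot_metrics(plots, land.chm, demo_config.plot_radius_m)


@pytest.fixture(scope="session")
def demo_models(demo_plots):
    from chmbiomass.calibration import calibrate_strata

    return calibrate_strata(
        demo_plots, candidate_heights=("h30", "h50", "h_mean"), min_plots=10
    )
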