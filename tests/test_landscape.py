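import dataclasses

import numpy as np
import pandas as pd
import pytest

from chmbiomass.landscape import (
    DegenerateStratumError,
    LandscapeConfig,
    LandscapeTruth,
    generate_landscape,
    sample_nfi_plots,
    true_scope_statistics,
)
from chmbiomass.raster import RasterGrid

from conftest import make_uniform_landscape


class TestConfigValidation:
    def test_extent_must_nest(self):
        with pytest.raises(ValueError, match="divisible by 100"):
            LandscapeConfig(extent_m=(1050.0, 1000.0))

    def test_gap_fraction_range(self):
        with pytest.raises(ValueError, match="gap_fraction"):
            LandscapeConfig(gap_fraction=1.0)

    def test_radius_vs_spacing(self):
        with pytest.raises(ValueError, match="plot_radius"):
            LandscapeConfig(plot_spacing_m=100.0, plot_radius_m=60.0)


class TestGenerate:
    def test_degenerate_field_constant_within_stratum(self):
        cfg = LandscapeConfig(
            extent_m=(400.0, 400.0), stratum_codes=(1, 2),
            mean_height_m=(5.0, 9.0), height_cv=0.0, gap_fraction=0.0,
            n_domains=1, seed=1,
        )
        land = generate_landscape(cfg)
        for code, mean in zip((1, 2), (5.0, 9.0)):
            h = land.chm.values[land.strata.values == code]
            assert np.all(h == mean)

    def test_determinism_same_seed(self):
        cfg = LandscapeConfig(extent_m=(400.0, 400.0), n_domains=2, seed=7,
                              stratum_codes=(1, 2), mean_height_m=10.0)
        a, b = generate_landscape(cfg), generate_landscape(cfg)
        assert np.array_equal(a.chm.values, b.chm.values)
        assert np.array_equal(a.strata.values, b.strata.values)
        assert np.array_equal(a.domains.values, b.domains.values)
        assert np.array_equal(a.truth.true_biomass.values, b.truth.true_biomass.values)

    def test_different_seed_differs(self):
        cfg = LandscapeConfig(extent_m=(400.0, 400.0), n_domains=1,
                              stratum_codes=(1,), mean_height_m=10.0, seed=1)
        cfg2 = dataclasses.replace(cfg, seed=2)
        assert not np.array_equal(
            generate_landscape(cfg).chm.values, generate_landscape(cfg2).chm.values
        )

    def test_heights_nonnegative_and_gaps_low(self):
        cfg = LandscapeConfig(extent_m=(600.0, 600.0), stratum_codes=(1,),
                              mean_height_m=12.0, gap_fraction=0.3, n_domains=1, seed=3)
        land = generate_landscape(cfg)
        h = land.chm.values
        assert np.all(h >= 0)
        gap_frac = np.mean(h < 0.5)
        assert gap_frac == pytest.approx(0.3, abs=0.02)

    def test_domains_tile_landscape(self):
        cfg = LandscapeConfig(extent_m=(600.0, 600.0), stratum_codes=(1,),
                              mean_height_m=10.0, n_domains=6, seed=0)
        land = generate_landscape(cfg)
        codes, counts = np.unique(land.domains.values, return_counts=True)
        assert list(codes) == list(range(1, 7))
        assert counts.sum() == land.domains.values.size

    def test_variogram_practical_range(self):
        # oracle: brute-force semivariogram on a strided 50x50 subsample
        cfg = LandscapeConfig(
            extent_m=(4000.0, 4000.0), stratum_codes=(1,), mean_height_m=10.0,
            height_cv=0.4, correlation_range_m=200.0, gap_fraction=0.0,
            n_domains=1, seed=11,
        )
        land = generate_landscape(cfg)
        # 50x50 = 2500 sampled cells scattered over the whole field so every
        # lag class is populated from many independent regions
        rng = np.random.default_rng(99)
        nr, nc = land.chm.values.shape
        rows = rng.integers(0, nr, 2500)
        cols = rng.integers(0, nc, 2500)
        z = land.chm.values[rows, cols]
        pts = np.column_stack([rows, cols]) * cfg.fine_cell_m
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        gsq = 0.5 * (z[:, None] - z[None, :]) ** 2
        iu = np.triu_indices(len(z), k=1)
        d, gsq = d[iu], gsq[iu]
        bins = np.arange(0, 520, 25.0)
        idx = np.digitize(d, bins)
        gamma = np.array([gsq[idx == k].mean() for k in range(1, len(bins))])
        sill = land.chm.values.var()  # full-field variance, unbiased for the sill
        reached = bins[1:][gamma >= 0.95 * sill]
        assert reached.size, "semivariogram never reached 95% of sill"
        assert abs(reached[0] - 200.0) / 200.0 <= 0.25

    def test_degenerate_stratum_error(self):
        # 100 strata on a tiny grid cannot all receive cells
        cfg = LandscapeConfig(
            extent_m=(100.0, 100.0), fine_cell_m=20.0,
            stratum_codes=tuple(range(1, 101)), mean_height_m=10.0,
            n_domains=1, seed=0,
        )
        with pytest.raises(DegenerateStratumError):
            generate_landscape(cfg)


class TestSamplePlots:
    def test_zero_chm_gives_empty_table(self):
        chm, strata, domains, truth = make_uniform_landscape(height=0.0)
        plots = sample_nfi_plots(
            chm, strata, domains, truth, spacing_m=100.0, radius_m=25.0,
            cover_min=0.10, cover_height_m=4.0, rng=0,
        )
        assert plots.empty

    def test_grid_count_without_filter(self):
        chm, strata, domains, truth = make_uniform_landscape(
            height=10.0, extent=4000.0, cell=2.0
        )
        # seed chosen so both offsets land in [25, 975]
        plots = sample_nfi_plots(
            chm, strata, domains, truth, spacing_m=1000.0, radius_m=25.0,
            cover_min=0.0, cover_height_m=4.0, rng=1,
        )
        assert len(plots) == 16

    def test_short_stratum_yields_no_plots(self):
        # stratum of 1-m vegetation never reaches 10% cover at the 4-m threshold
        cfg = LandscapeConfig(
            extent_m=(800.0, 800.0), stratum_codes=(1, 2),
            mean_height_m=(1.0, 12.0), height_cv=0.0, gap_fraction=0.0,
            n_domains=1, plot_spacing_m=100.0, seed=5,
        )
        land = generate_landscape(cfg)
        plots = sample_nfi_plots(
            land.chm, land.strata, land.domains, land.truth,
            spacing_m=100.0, radius_m=25.0, cover_min=0.10, cover_height_m=4.0,
            rng=3,
        )
        assert not plots.empty
        assert not (plots.stratum == 1).any()

    def test_radius_smaller_than_cell_rejected(self):
        chm, strata, domains, truth = make_uniform_landscape(cell=2.0)
        with pytest.raises(ValueError, match="radius"):
            sample_nfi_plots(
                chm, strata, domains, truth, spacing_m=100.0, radius_m=1.0, rng=0
            )

    def test_plot_agbd_matches_footprint_truth_when_noiseless(self):
        chm, strata, domains, truth = make_uniform_landscape(height=10.0, biomass=80.0)
        plots = sample_nfi_plots(
            chm, strata, domains, truth, spacing_m=100.0, radius_m=25.0,
            cover_min=0.0, cover_height_m=4.0, noise_cv=0.0, rng=0,
        )
        assert np.allclose(plots.agbd_mg_ha, 80.0)

    def test_sampling_validity_over_offsets(self):
        # noiseless, unfiltered sampling is unbiased for the stratum mean
        cfg = LandscapeConfig(
            extent_m=(2000.0, 2000.0), stratum_codes=(1, 2),
            mean_height_m=(8.0, 14.0), height_cv=0.4, gap_fraction=0.1,
            correlation_range_m=100.0, n_domains=1, seed=9,
        )
        land = generate_landscape(cfg)
        rng = np.random.default_rng(123)
        sums: dict[int, list[float]] = {}
        for _ in range(120):
            plots = sample_nfi_plots(
                land.chm, land.strata, land.domains, land.truth,
                spacing_m=100.0, radius_m=25.0, cover_min=0.0,
                cover_height_m=4.0, noise_cv=0.0, rng=rng,
            )
            for code, grp in plots.groupby("stratum"):
                sums.setdefault(int(code), []).extend(grp.agbd_mg_ha)
        for code, vals in sums.items():
            truth_mean = land.truth.true_mean("stratum", code)
            assert abs(np.mean(vals) - truth_mean) / truth_mean < 0.02


class TestTrueScopeStatistics:
    def test_uniform_total(self):
        # 100 Mg/ha over a 100-ha (1000 m x 1000 m) single-stratum landscape
        chm, strata, domains, truth = make_uniform_landscape(
            height=10.0, extent=1000.0, cell=2.0, biomass=100.0
        )
        assert truth.true_total("stratum", 101) == pytest.approx(10_000.0)

    def test_two_cell_mean(self):
        vals = np.array([[50.0, 150.0]])
        g = RasterGrid((0.0, 0.0), 100.0, vals)
        labs = RasterGrid((0.0, 0.0), 100.0, np.array([[1, 1]], dtype=np.int16), nodata=-1)
        stats = true_scope_statistics(g, labs, labs)
        row = stats[(stats.scope_type == "stratum") & (stats.scope_id == "1")]
        assert row.true_mean.iloc[0] == pytest.approx(100.0)

    def test_partition_conservation(self, demo_landscape):
        stats = demo_landscape.truth.scope_stats
        total = stats[stats.scope_type == "landscape"].true_total.iloc[0]
        for scope in ("stratum", "domain", "stratum_x_domain"):
            part = stats[stats.scope_type == scope].true_total.sum()
            assert part == pytest.approx(total, rel=1e-6)
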