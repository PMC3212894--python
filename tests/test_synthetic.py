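import numpy as np
import pandas as pd
import pytest

from stratiforest import (
    LandscapeConfig,
    StemMap,
    limiting_distance,
    simulate_landscape,
    simulate_prism_plot,
)


def brute_force_tally(trees: pd.DataFrame, x0: float, y0: float, baf: float, min_dbh: float):
    """Independent oracle: scan every tree against BAF = 2500 (D/R)^2."""
    keep = []
    for i, t in trees.iterrows():
        if t.dbh_cm < min_dbh:
            continue
        r = np.hypot(t.x - x0, t.y - y0)
        d_m = t.dbh_cm / 100.0
        if r == 0 or 2500.0 * (d_m / r) ** 2 >= baf:
            keep.append(i)
    return set(keep)


class TestLimitingDistance:
    def test_closed_form_40cm(self):
        # from BAF = 2500 (D/R)^2: R = 50 * 0.40 / sqrt(4.6)
        oracle = 50.0 * 0.40 / np.sqrt(4.6)
        assert limiting_distance(40.0, 4.6) == pytest.approx(oracle, abs=1e-12)
        assert limiting_distance(40.0, 4.6) == pytest.approx(9.325, abs=5e-4)

    def test_small_dbh_limit(self):
        assert limiting_distance(1e-9, 4.6) < 1e-9

    def test_linear_in_dbh(self):
        assert limiting_distance(80.0, 4.6) == pytest.approx(2 * limiting_distance(40.0, 4.6))

    @pytest.mark.parametrize("dbh,baf", [(0.0, 4.6), (-5.0, 4.6), (40.0, 0.0), (40.0, -1.0)])
    def test_domain_errors(self, dbh, baf):
        with pytest.raises(ValueError):
            limiting_distance(dbh, baf)


class TestConfigValidation:
    def test_extent_smaller_than_cell(self):
        with pytest.raises(ValueError, match="extent"):
            LandscapeConfig(extent_m=(10.0, 10.0), cell_size_m=20.0)

    def test_negative_sd(self):
        with pytest.raises(ValueError):
            LandscapeConfig(ba_sd=-1.0)

    def test_zero_cell_size(self):
        with pytest.raises(ValueError):
            LandscapeConfig(cell_size_m=0.0)


class TestDeterminism:
    def test_same_seed_identical_stem_maps(self):
        cfg = LandscapeConfig(extent_m=(200.0, 200.0), seed=7, chm_pixel_m=2.0, image_pixel_m=2.0)
        a = simulate_landscape(cfg)
        b = simulate_landscape(cfg)
        assert a.stem_map.checksum() == b.stem_map.checksum()
        for name in a.rasters:
            np.testing.assert_array_equal(a.rasters[name].data, b.rasters[name].data)

    def test_different_seed_differs(self):
        base = dict(extent_m=(200.0, 200.0), chm_pixel_m=2.0, image_pixel_m=2.0)
        a = simulate_landscape(LandscapeConfig(seed=1, **base))
        b = simulate_landscape(LandscapeConfig(seed=2, **base))
        assert a.stem_map.checksum() != b.stem_map.checksum()


class TestAggregationConsistency:
    def test_truth_ba_matches_stems(self, small_landscape):
        L = small_landscape
        t = L.stem_map.trees
        agg = (
            t.assign(ba=np.pi * (t.dbh_cm / 200.0) ** 2).groupby("cell_id")["ba"].sum()
            / L.grid.cell_area_ha
        )
        for cid, v in agg.items():
            r, c = divmod(cid, L.grid.n_cols)
            assert abs(v - L.truth.ba[r, c]) < 1e-9

    def test_truth_tph_matches_counts(self, small_landscape):
        L = small_landscape
        counts = L.stem_map.trees.groupby("cell_id").size()
        for cid, n in counts.items():
            r, c = divmod(cid, L.grid.n_cols)
            assert L.truth.tph[r, c] == pytest.approx(n / L.grid.cell_area_ha)

    def test_field_bounds(self, small_landscape):
        L = small_landscape
        assert (L.truth.ba >= 0).all()
        assert (L.truth.tph >= 0).all()
        assert ((L.truth.pct_conifer >= 0) & (L.truth.pct_conifer <= 100)).all()

    def test_stems_inside_extent(self, small_landscape):
        t = small_landscape.stem_map.trees
        w, h = small_landscape.config.extent_m
        assert ((t.x >= 0) & (t.x <= w) & (t.y >= 0) & (t.y <= h)).all()


class TestRasters:
    def test_chm_correlates_with_truth_height(self, small_landscape):
        L = small_landscape
        chm = L.rasters["chm"]
        idx = chm.cell_index_of_pixels(L.grid)
        means = np.array(
            [chm.data[idx == cid].mean() for cid in range(L.grid.n_cells)]
        ).reshape(L.truth.height.shape)
        r = np.corrcoef(means.ravel(), L.truth.height.ravel())[0, 1]
        assert r > 0.5

    def test_bands_monotone_in_ba(self, small_landscape):
        L = small_landscape
        band = L.rasters["cir_ir"]
        idx = band.cell_index_of_pixels(L.grid)
        means = np.array([band.data[idx == cid].mean() for cid in range(L.grid.n_cells)])
        r = np.corrcoef(means, L.truth.ba.ravel())[0, 1]
        assert r > 0.4


def _empirical_corr_range(field: np.ndarray, max_lag: int = 15) -> int:
    """Oracle: first row/col lag where spatial autocorrelation drops below 0.3."""
    z = field - field.mean()
    for lag in range(1, max_lag + 1):
        a = np.corrcoef(z[:, :-lag].ravel(), z[:, lag:].ravel())[0, 1]
        b = np.corrcoef(z[:-lag, :].ravel(), z[lag:, :].ravel())[0, 1]
        if 0.5 * (a + b) < 0.3:
            return lag
    return max_lag + 1


class TestSpatialCorrelation:
    def test_longer_range_config_gives_longer_empirical_range(self):
        base = dict(
            extent_m=(1200.0, 1200.0),
            chm_pixel_m=6.0,
            image_pixel_m=6.0,
            dem_pixel_m=6.0,
            tph_mean=150.0,
            seed=3,
        )
        long_cfg = LandscapeConfig(spatial_corr_range_m=300.0, **base)
        short_cfg = LandscapeConfig(spatial_corr_range_m=40.0, **base)
        long_range = _empirical_corr_range(simulate_landscape(long_cfg).truth.ba)
        short_range = _empirical_corr_range(simulate_landscape(short_cfg).truth.ba)
        assert long_range > short_range


class TestPrismPlot:
    @pytest.fixture()
    def one_tree(self):
        def make(distance: float, dbh: float = 40.0) -> StemMap:
            return StemMap(
                pd.DataFrame(
                    {
                        "x": [50.0 + distance],
                        "y": [50.0],
                        "species": ["CON"],
                        "conifer": [True],
                        "dbh_cm": [dbh],
                        "height_m": [25.0],
                        "live": [True],
                    }
                )
            )

        return make

    def test_tree_inside_limiting_distance_tallied(self, one_tree):
        plot = simulate_prism_plot(one_tree(9.0), (50.0, 50.0), baf=4.6, gps_error_95_m=0.0)
        assert plot.tally_count == 1

    def test_tree_outside_limiting_distance_not_tallied(self, one_tree):
        plot = simulate_prism_plot(one_tree(9.5), (50.0, 50.0), baf=4.6, gps_error_95_m=0.0)
        assert plot.tally_count == 0

    def test_small_tree_filtered(self, one_tree):
        plot = simulate_prism_plot(
            one_tree(1.0, dbh=10.0), (50.0, 50.0), baf=4.6, min_dbh_cm=14.0, gps_error_95_m=0.0
        )
        assert plot.tally_count == 0

    def test_empty_stem_map(self):
        empty = StemMap(
            pd.DataFrame(columns=["x", "y", "species", "conifer", "dbh_cm", "height_m", "live"])
        )
        plot = simulate_prism_plot(empty, (10.0, 10.0), baf=4.6, gps_error_95_m=0.0)
        assert plot.tally_count == 0

    def test_matches_brute_force_oracle(self, small_landscape, rng):
        L = small_landscape
        for _ in range(20):
            x0, y0 = rng.uniform(50, 350, size=2)
            plot = simulate_prism_plot(
                L.stem_map, (x0, y0), baf=4.6, min_dbh_cm=14.0, gps_error_95_m=0.0
            )
            oracle = brute_force_tally(L.stem_map.trees, x0, y0, 4.6, 14.0)
            assert plot.tally_count == len(oracle)

    def test_gps_jitter_calibration(self):
        # fraction of realized centers within the 95% radius must be 0.95 +/- 0.01
        empty = StemMap(
            pd.DataFrame(columns=["x", "y", "species", "conifer", "dbh_cm", "height_m", "live"])
        )
        rng = np.random.default_rng(42)
        hits = 0
        n = 10_000
        for _ in range(n):
            p = simulate_prism_plot(empty, (0.0, 0.0), baf=4.6, gps_error_95_m=10.0, rng=rng)
            if np.hypot(p.realized_x, p.realized_y) <= 10.0:
                hits += 1
        assert abs(hits / n - 0.95) <= 0.01

    def test_realized_center_stored(self):
        empty = StemMap(
            pd.DataFrame(columns=["x", "y", "species", "conifer", "dbh_cm", "height_m", "live"])
        )
        p = simulate_prism_plot(empty, (5.0, 6.0), baf=4.6, gps_error_95_m=0.0)
        assert (p.realized_x, p.realized_y) == (5.0, 6.0)


class TestDegenerateNoiseless:
    def test_constant_fields_and_perfect_model(self):
        cfg = LandscapeConfig(
            extent_m=(200.0, 200.0),
            ba_sd=0.0,
            tph_sd=0.0,
            conifer_logit_sd=0.0,
            image_noise_sd=0.0,
            seed=9,
            chm_pixel_m=2.0,
            image_pixel_m=2.0,
        )
        L = simulate_landscape(cfg)
        assert np.allclose(L.truth.ba, L.truth.ba.flat[0])
        assert np.allclose(L.truth.tph, L.truth.tph.flat[0])
        band = L.rasters["cir_ir"].data
        assert np.allclose(band, band.flat[0])
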