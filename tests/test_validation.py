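import numpy as np
import pytest
from shapely.geometry import box

from agbmc import (
    PlotRecord,
    Zone,
    fit_stats,
    forest_fraction_for_zones,
    hex_mesh,
    stratified_split,
    zonal_weighted_validation,
    zones_from_geojson,
    zones_to_geojson,
)


def _plots(agb_values, xy=None):
    out = []
    for i, v in enumerate(agb_values):
        x, y = xy[i] if xy is not None else (float(i), float(i))
        out.append(PlotRecord(plot_id=i, x=x, y=y, subplot_agb=(v,) * 4,
                              agb=float(v), slope_deg=0.0))
    return out


class TestStratifiedSplit:
    def test_single_class_67_33(self):
        plots = _plots(np.full(100, 15.0))
        cal, val = stratified_split(plots, cal_fraction=0.67, seed=1)
        assert len(cal) == 67 and len(val) == 33

    def test_is_partition_and_reproducible(self, rng):
        plots = _plots(rng.uniform(0, 300, 500))
        cal1, val1 = stratified_split(plots, seed=9)
        cal2, val2 = stratified_split(plots, seed=9)
        ids = sorted(p.plot_id for p in cal1 + val1)
        assert ids == list(range(500))
        assert not set(p.plot_id for p in cal1) & set(p.plot_id for p in val1)
        assert [p.plot_id for p in cal1] == [p.plot_id for p in cal2]

    def test_per_class_fraction_converges(self, rng):
        plots = _plots(rng.uniform(0, 300, 10_000))
        cal, val = stratified_split(plots, class_width=30.0, n_classes=10,
                                    cal_fraction=0.67, seed=3)
        agb = np.array([p.agb for p in cal + val])
        cal_flag = np.array([1] * len(cal) + [0] * len(val))
        for c in range(10):
            in_class = (np.minimum(agb // 30, 9).astype(int)) == c
            frac = cal_flag[in_class].mean()
            assert frac == pytest.approx(0.67, abs=0.01)

    def test_empty_input(self):
        assert stratified_split([]) == ([], [])


class TestFitStats:
    def test_perfect_prediction(self):
        obs = np.array([1.0, 5.0, 9.0])
        s = fit_stats(obs, obs)
        assert (s.r2, s.rmse, s.bias) == (pytest.approx(1.0), 0.0, 0.0)

    def test_constant_offset(self):
        obs = np.array([1.0, 5.0, 9.0])
        s = fit_stats(obs, obs + 5)
        assert s.r2 == pytest.approx(1.0)
        assert s.rmse == pytest.approx(5.0)
        assert s.bias == pytest.approx(5.0)

    def test_anticorrelated_pair(self):
        s = fit_stats(np.array([0.0, 10.0]), np.array([10.0, 0.0]))
        assert s.r2 == pytest.approx(1.0)
        assert s.bias == pytest.approx(0.0)
        assert s.rmse == pytest.approx(10.0)

    def test_zero_variance_flags_r2(self):
        s = fit_stats(np.array([5.0, 5.0]), np.array([4.0, 6.0]))
        assert not s.r2_defined and np.isnan(s.r2)
        assert s.rmse == pytest.approx(np.sqrt(1.0))

    def test_rmse_dominates_bias(self, rng):
        obs = rng.uniform(0, 100, 50)
        pred = obs + rng.normal(3, 10, 50)
        s = fit_stats(obs, pred)
        assert s.rmse >= abs(s.bias)


class TestHexMesh:
    def test_interior_cell_has_requested_area(self):
        zones = hex_mesh((0, 0, 10_000, 10_000), hex_area=1_000_000.0)
        areas = [z.geometry.area for z in zones]
        interior = [a for a in areas if a == pytest.approx(1_000_000.0, rel=1e-6)]
        assert interior, "expected at least one unclipped hexagon"

    def test_tiny_bounds_single_clipped_zone(self):
        zones = hex_mesh((0, 0, 10, 10), hex_area=1e6)
        assert len(zones) >= 1
        assert all(z.geometry.area <= 100.0 + 1e-6 for z in zones)

    def test_tessellation_covers_bounds_without_overlap(self):
        bounds = (0, 0, 5000, 4000)
        zones = hex_mesh(bounds, hex_area=500_000.0)
        total = sum(z.geometry.area for z in zones)
        assert total == pytest.approx(5000 * 4000, rel=1e-6)

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError):
            hex_mesh((0, 0, 0, 10), 100.0)


class TestZonalValidation:
    def test_perfect_map_single_zone(self):
        zone = Zone(geometry=box(0, 0, 400, 400), zone_id=0, forest_fraction=1.0)
        map_mean = np.full((4, 4), 50.0)
        plots = _plots([50.0, 50.0], xy=[(150, 150), (250, 250)])
        pairs, stats = zonal_weighted_validation(map_mean, plots, [zone],
                                                 pixel_size=100.0)
        assert len(pairs) == 1
        assert pairs[0]["obs"] == pytest.approx(pairs[0]["pred"]) == pytest.approx(50.0)

    def test_zero_forest_fraction_dropped(self):
        zone = Zone(geometry=box(0, 0, 400, 400), zone_id=0, forest_fraction=0.0)
        map_mean = np.full((4, 4), 50.0)
        plots = _plots([50.0], xy=[(150, 150)])
        pairs, _ = zonal_weighted_validation(map_mean, plots, [zone], 100.0)
        assert pairs == []

    def test_two_zone_means_match_direct_averaging(self):
        map_mean = np.arange(16, dtype=float).reshape(4, 4)
        z1 = Zone(geometry=box(0, 0, 200, 400), zone_id=1, forest_fraction=0.5)
        z2 = Zone(geometry=box(200, 0, 400, 400), zone_id=2, forest_fraction=1.0)
        plots = _plots([10.0, 20.0, 40.0],
                       xy=[(50, 50), (150, 350), (250, 150)])
        pairs, stats = zonal_weighted_validation(map_mean, plots, [z1, z2], 100.0)
        by_id = {p["zone_id"]: p for p in pairs}
        # zone 1: map cols 0-1, mean of [0,1,4,5,8,9,12,13] = 6.5, weight 0.5
        assert by_id[1]["pred"] == pytest.approx(6.5 * 0.5)
        assert by_id[1]["obs"] == pytest.approx(15.0 * 0.5)
        # zone 2: map cols 2-3, mean = 8.5, weight 1.0
        assert by_id[2]["pred"] == pytest.approx(8.5)
        assert by_id[2]["obs"] == pytest.approx(40.0)
        assert stats.n == 2

    def test_single_pixel_zones_degenerate_to_pixel_stats(self, rng):
        vals = rng.uniform(10, 100, 9).reshape(3, 3)
        zones, plots = [], []
        for r in range(3):
            for c in range(3):
                zones.append(Zone(geometry=box(c * 100, r * 100,
                                               (c + 1) * 100, (r + 1) * 100),
                                  zone_id=r * 3 + c, forest_fraction=1.0))
                plots.append(PlotRecord(plot_id=r * 3 + c, x=c * 100 + 50,
                                        y=r * 100 + 50, subplot_agb=(0,) * 4,
                                        agb=float(vals[r, c]) + 1.0, slope_deg=0.0))
        pairs, stats = zonal_weighted_validation(vals, plots, zones, 100.0)
        assert len(pairs) == 9
        assert stats.bias == pytest.approx(-1.0)
        assert stats.r2 == pytest.approx(1.0)

    def test_nodata_zone_dropped(self):
        zone = Zone(geometry=box(0, 0, 200, 200), zone_id=0)
        map_mean = np.full((2, 2), np.nan)
        plots = _plots([50.0], xy=[(100, 100)])
        pairs, _ = zonal_weighted_validation(map_mean, plots, [zone], 100.0)
        assert pairs == []


class TestZoneIo:
    def test_geojson_round_trip(self, tmp_path):
        zones = hex_mesh((0, 0, 3000, 3000), hex_area=1e6)
        path = tmp_path / "zones.geojson"
        zones_to_geojson(zones, path)
        back = zones_from_geojson(path)
        assert len(back) == len(zones)
        assert back[0].geometry.area == pytest.approx(zones[0].geometry.area)

    def test_forest_fraction_from_mask(self):
        forest = np.zeros((4, 4), dtype=bool)
        forest[:2, :2] = True
        zones = [Zone(geometry=box(0, 0, 400, 400), zone_id=0)]
        out = forest_fraction_for_zones(zones, forest, pixel_size=100.0)
        assert out[0].forest_fraction == pytest.approx(4 / 16)
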