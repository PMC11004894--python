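"""Synthetic yield-monitor generator: geometry, surface, and measurement laws."""

import numpy as np
import pandas as pd
import pytest

from yieldbayes import (CONTROL, TEST, DegenerateGeometryError, FieldLayout,
                        SimulationConfig, make_layouts, segment_polygons,
                        simulate_fertility_surface, simulate_measurements)


def quiet_config(**kw):
    base = dict(fertility_sd=0.0, noise_sd=0.0, outlier_rate=0.0,
                treatment_effect=0.0)
    base.update(kw)
    return SimulationConfig(**base)


class TestSegmentPolygons:
    def test_interior_area_is_product_of_swath_speed_interval(self):
        cfg = quiet_config(swath_width=2.0, harvester_speed=1.0,
                           measurement_interval=1.0)
        polys = segment_polygons(FieldLayout("f", TEST, width=10, length=8), cfg)
        assert np.allclose(polys["area_m2"], 2.0)

    @pytest.mark.parametrize("width,length", [
        (10.0, 8.0),        # exact tiling
        (10.5, 8.3),        # truncated edge strips in both dimensions
        (3.1, 100.0),       # single column plus sliver
    ])
    def test_tiling_conserves_field_area(self, width, length):
        cfg = quiet_config(swath_width=3.0, harvester_speed=0.5,
                           measurement_interval=4.0)
        layout = FieldLayout("f", CONTROL, origin=(7.0, -3.0),
                             width=width, length=length)
        polys = segment_polygons(layout, cfg)
        assert polys["area_m2"].sum() == pytest.approx(width * length, rel=1e-12)

    def test_centroids_inside_field(self):
        cfg = quiet_config(swath_width=3.0, harvester_speed=1.0,
                           measurement_interval=2.5)
        layout = FieldLayout("f", TEST, origin=(100.0, 50.0), width=10.4,
                             length=21.7)
        polys = segment_polygons(layout, cfg)
        assert ((polys["x"] > 100.0) & (polys["x"] < 110.4)).all()
        assert ((polys["y"] > 50.0) & (polys["y"] < 71.7)).all()

    def test_no_overlap_full_cover(self):
        # centroids are unique and counts match an exhaustive grid walk
        cfg = quiet_config(swath_width=2.0, harvester_speed=1.0,
                           measurement_interval=3.0)
        layout = FieldLayout("f", TEST, width=7.0, length=13.0)
        polys = segment_polygons(layout, cfg)
        n_cols = int(np.ceil(7.0 / 2.0))
        n_rows = int(np.ceil(13.0 / 3.0))
        assert len(polys) == n_cols * n_rows
        assert len(polys[["x", "y"]].drop_duplicates()) == len(polys)

    def test_field_smaller_than_one_polygon_raises(self):
        cfg = quiet_config(swath_width=5.0, harvester_speed=1.0,
                           measurement_interval=1.0)
        with pytest.raises(DegenerateGeometryError):
            segment_polygons(FieldLayout("f", TEST, width=4.0, length=100), cfg)


class TestFertilitySurface:
    def test_zero_sd_gives_flat_zero_surface(self, rng):
        cfg = quiet_config(fertility_sd=0.0)
        surf = simulate_fertility_surface(
            [FieldLayout("f", TEST, width=100, length=100)], cfg)
        x, y = rng.uniform(0, 100, 50), rng.uniform(0, 100, 50)
        assert np.all(surf(x, y) == 0.0)

    def test_marginal_sd_matches_configuration(self, rng):
        cfg = quiet_config(fertility_sd=300.0, fertility_scale=40.0, seed=11)
        surf = simulate_fertility_surface(
            [FieldLayout("f", TEST, width=2000, length=2000)], cfg)
        x, y = rng.uniform(0, 2000, 10_000), rng.uniform(0, 2000, 10_000)
        sd = surf(x, y).std()
        assert abs(sd - 300.0) / 300.0 < 0.10

    def test_nearby_points_positively_correlated(self, rng):
        cfg = quiet_config(fertility_sd=100.0, fertility_scale=50.0, seed=5)
        surf = simulate_fertility_surface(
            [FieldLayout("f", TEST, width=3000, length=300)], cfg)
        x = rng.uniform(0, 3000, 4000)
        y = rng.uniform(0, 300, 4000)
        near = surf(x + 10.0, y)  # 10 m apart, well inside the 50 m scale
        corr = np.corrcoef(surf(x, y), near)[0, 1]
        assert corr > 0.5

    def test_same_seed_bit_identical(self, rng):
        cfg = quiet_config(fertility_sd=250.0, seed=42)
        layouts = [FieldLayout("f", TEST, width=500, length=500)]
        a = simulate_fertility_surface(layouts, cfg)
        b = simulate_fertility_surface(layouts, cfg)
        x, y = rng.uniform(0, 500, 200), rng.uniform(0, 500, 200)
        assert np.array_equal(a(x, y), b(x, y))


class TestSimulateMeasurements:
    def test_all_randomness_off_yields_baseline_exactly(self):
        cfg = quiet_config(baseline_mean=2550.0)
        df = simulate_measurements(make_layouts_small(), cfg)
        assert np.all(df["dry_yield_kg_ha"].to_numpy() == 2550.0)

    def test_treatment_effect_recovered_within_three_se(self):
        cfg = SimulationConfig(baseline_mean=2550.0, treatment_effect=1000.0,
                               fertility_sd=0.0, noise_sd=400.0,
                               outlier_rate=0.0, seed=7)
        df = simulate_measurements(make_layouts_small(width=98, length=400), cfg)
        t = df.loc[df.group == TEST, "dry_yield_kg_ha"]
        c = df.loc[df.group == CONTROL, "dry_yield_kg_ha"]
        se = np.sqrt(t.var(ddof=1) / len(t) + c.var(ddof=1) / len(c))
        assert abs((t.mean() - c.mean()) - 1000.0) < 3 * se

    def test_fixed_seed_identical_dataset(self):
        cfg = SimulationConfig(seed=9)
        layouts = make_layouts_small()
        pd.testing.assert_frame_equal(simulate_measurements(layouts, cfg),
                                      simulate_measurements(layouts, cfg))

    def test_group_labels_partition_as_layouts_specify(self):
        cfg = SimulationConfig(seed=1)
        layouts = make_layouts(3, 2, width=60, length=90)
        df = simulate_measurements(layouts, cfg)
        by_layout = {f.field_id: f.group for f in layouts}
        per_field = df.groupby("field_id")["group"].unique()
        assert all(len(v) == 1 and v[0] == by_layout[k]
                   for k, v in per_field.items())

    def test_yields_never_negative_even_with_huge_noise(self):
        cfg = SimulationConfig(baseline_mean=100.0, noise_sd=2000.0,
                               fertility_sd=0.0, outlier_rate=0.0, seed=3)
        df = simulate_measurements(make_layouts_small(), cfg)
        assert (df["dry_yield_kg_ha"] >= 0).all()

    def test_outliers_injected_at_configured_magnitude(self):
        cfg = SimulationConfig(baseline_mean=5000.0, treatment_effect=0.0,
                               fertility_sd=0.0, noise_sd=100.0,
                               outlier_rate=0.5, outlier_magnitude=8.0, seed=2)
        df = simulate_measurements(make_layouts_small(width=98, length=400), cfg)
        dev = (df["dry_yield_kg_ha"] - 5000.0).abs()
        frac_gross = (dev == 800.0).mean()
        assert 0.4 < frac_gross < 0.6

    def test_requires_both_groups(self):
        cfg = SimulationConfig()
        with pytest.raises(ValueError):
            simulate_measurements([FieldLayout("a", TEST, width=60, length=90)],
                                  cfg)
        with pytest.raises(ValueError):
            simulate_measurements([], cfg)


def make_layouts_small(width=56, length=98):
    return make_layouts(1, 1, width=width, length=length)


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(swath_width=0.0)
    with pytest.raises(ValueError):
        SimulationConfig(outlier_rate=1.5)
    with pytest.raises(ValueError):
        FieldLayout("f", "treated", width=10, length=10)
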