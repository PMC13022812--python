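import numpy as np
import pytest

from seasonsdm import (LAYERS, MLP, NicheMaps, SEASONS, ShiftReport, GridSpec,
                       Standardizer, SeasonalModelSet, change_map, predict_points,
                       project_niche, scenario_agreement, shift_stats)


@pytest.fixture(scope="module")
def toy_model_set(random_stack):
    """A small M1 set with untrained (but fixed) weights and thresholds."""
    rng = np.random.default_rng(0)
    X = rng.normal(size=(50, 9))
    models = {s: MLP.init(9, (8, 8), seed=i) for i, s in enumerate(SEASONS)}
    stds = {s: Standardizer.fit(X) for s in SEASONS}
    return SeasonalModelSet("M1", models, standardizers=stds,
                            thresholds={s: 0.5 for s in SEASONS})


def _maps_from_binary(grid, binary):
    prob = {s: binary[s].astype(float) for s in SEASONS}
    return NicheMaps(grid, prob, {s: binary[s].astype(bool) for s in SEASONS})


class TestProjectNiche:
    def test_constant_model_gives_constant_maps(self, random_stack):
        models = {s: MLP.init(9, seed=0) for s in SEASONS}
        for s in SEASONS:
            for p in models[s].params:
                p[...] = 0.0
        stds = {s: Standardizer.fit(np.random.default_rng(0).normal(size=(10, 9)))
                for s in SEASONS}
        ms = SeasonalModelSet("M1", models, standardizers=stds,
                              thresholds={s: 0.4 for s in SEASONS})
        maps = project_niche(ms, random_stack)
        for s in SEASONS:
            np.testing.assert_array_equal(maps.probability[s], 0.5)
            assert maps.binary[s].all()

    def test_repeat_calls_identical(self, toy_model_set, random_stack):
        a = project_niche(toy_model_set, random_stack)
        b = project_niche(toy_model_set, random_stack)
        for s in SEASONS:
            np.testing.assert_array_equal(a.probability[s], b.probability[s])

    def test_cells_equal_pointwise_predictions(self, toy_model_set, random_stack):
        """Raster values equal individual point predictions on a toy grid."""
        from seasonsdm import cell_center
        maps = project_niche(toy_model_set, random_stack)
        rng = np.random.default_rng(1)
        rows = rng.integers(0, random_stack.grid.n_rows, 5)
        cols = rng.integers(0, random_stack.grid.n_cols, 5)
        lat, lon = cell_center(rows, cols, random_stack.grid)
        pts = np.column_stack([lat, lon])
        p = predict_points(toy_model_set, pts, random_stack)
        for s in SEASONS:
            np.testing.assert_allclose(maps.probability[s][rows, cols], p[s],
                                       atol=1e-14)

    def test_derived_layers_are_union_and_intersection(self, toy_model_set,
                                                       random_stack):
        maps = project_niche(toy_model_set, random_stack)
        seasonal = np.stack([maps.binary[s] for s in SEASONS])
        np.testing.assert_array_equal(maps.any_season, seasonal.any(axis=0))
        np.testing.assert_array_equal(maps.year_round, seasonal.all(axis=0))
        assert (maps.year_round <= maps.any_season).all()

    def test_missing_thresholds_is_state_error(self, toy_model_set, random_stack):
        ms = SeasonalModelSet("M1", toy_model_set.models,
                              standardizers=toy_model_set.standardizers)
        with pytest.raises(RuntimeError):
            project_niche(ms, random_stack)


class TestChangeMap:
    def _binary(self, grid, cells):
        b = np.zeros(grid.shape, dtype=bool)
        for r, c in cells:
            b[r, c] = True
        return {s: b for s in SEASONS}

    def test_identical_periods_no_change(self, small_grid):
        m = _maps_from_binary(small_grid, self._binary(small_grid, [(1, 1), (2, 2)]))
        out = change_map(m, m, "spring")
        assert out.lost_pct == 0 and out.gained_pct == 0

    def test_hand_counted_percentages(self, small_grid):
        present_cells = [(i, 0) for i in range(10)]
        future_cells = present_cells[3:] + [(i, 5) for i in range(5)]
        present = _maps_from_binary(small_grid, self._binary(small_grid, present_cells))
        future = _maps_from_binary(small_grid, self._binary(small_grid, future_cells))
        out = change_map(present, future, "summer")
        assert out.lost_pct == pytest.approx(30.0)
        assert out.gained_pct == pytest.approx(50.0)

    def test_empty_present_flagged_undefined(self, small_grid):
        present = _maps_from_binary(small_grid, self._binary(small_grid, []))
        future = _maps_from_binary(small_grid, self._binary(small_grid, [(0, 0)]))
        out = change_map(present, future, "fall")
        assert out.lost_pct is None and out.gained_pct is None

    def test_matches_per_cell_loop_and_conservation(self, small_grid):
        rng = np.random.default_rng(2)
        a = rng.random(small_grid.shape) < 0.4
        b = rng.random(small_grid.shape) < 0.4
        present = NicheMaps(small_grid, {s: a.astype(float) for s in SEASONS},
                            {s: a for s in SEASONS})
        future = NicheMaps(small_grid, {s: b.astype(float) for s in SEASONS},
                           {s: b for s in SEASONS})
        out = change_map(present, future, "winter")
        for i in range(small_grid.n_rows):
            for j in range(small_grid.n_cols):
                assert out.lost[i, j] == (a[i, j] and not b[i, j])
                assert out.gained[i, j] == (b[i, j] and not a[i, j])
        assert a.sum() - out.lost.sum() + out.gained.sum() == b.sum()

    def test_grid_mismatch_rejected(self, small_grid):
        other = GridSpec(0, 4, 0, 4, 0.5)
        a = _maps_from_binary(small_grid, self._binary(small_grid, [(0, 0)]))
        bmask = np.zeros(other.shape, dtype=bool)
        b = NicheMaps(other, {s: bmask.astype(float) for s in SEASONS},
                      {s: bmask for s in SEASONS})
        with pytest.raises(ValueError):
            change_map(a, b, "spring")


class TestShiftStats:
    def test_single_cell_statistics_are_its_center(self, small_grid):
        b = np.zeros(small_grid.shape, dtype=bool)
        b[3, 4] = True
        out = shift_stats(b, small_grid)
        assert out["latitude"]["median"] == pytest.approx(1.75)
        assert out["latitude"]["p5"] == out["latitude"]["p95"] == pytest.approx(1.75)
        assert out["longitude"]["median"] == pytest.approx(2.25)

    def test_two_cell_median(self, small_grid):
        b = np.zeros(small_grid.shape, dtype=bool)
        b[0, 0] = b[8, 0] = True   # centers at lat 0.25 and 4.25
        out = shift_stats(b, small_grid)
        assert out["latitude"]["median"] == pytest.approx(2.25)

    def test_matches_independent_sort_based_percentiles(self, small_grid):
        rng = np.random.default_rng(3)
        b = rng.random(small_grid.shape) < 0.3
        b[0, 0] = True
        out = shift_stats(b, small_grid)
        lats = np.sort([small_grid.lat_min + (r + 0.5) * small_grid.cell_size
                        for r, c in zip(*np.nonzero(b))])
        for q, key in ((5, "p5"), (50, "median"), (95, "p95")):
            # linear-interpolation percentile on the sorted sample
            h = (len(lats) - 1) * q / 100
            lo, hi = int(np.floor(h)), int(np.ceil(h))
            expected = lats[lo] + (h - lo) * (lats[hi] - lats[lo])
            assert out["latitude"][key] == pytest.approx(expected)

    def test_translation_equivariance(self, small_grid):
        """Shifting all suitable cells north by k rows adds k * cell_size to
        every latitude statistic."""
        b = np.zeros(small_grid.shape, dtype=bool)
        b[1:4, 2:5] = True
        shifted = np.roll(b, 3, axis=0)
        a = shift_stats(b, small_grid)
        c = shift_stats(shifted, small_grid)
        for key in ("p5", "median", "p95"):
            assert c["latitude"][key] - a["latitude"][key] == pytest.approx(1.5)
            assert c["longitude"][key] == pytest.approx(a["longitude"][key])

    def test_empty_map_rejected(self, small_grid):
        with pytest.raises(ValueError):
            shift_stats(np.zeros(small_grid.shape, dtype=bool), small_grid)


class TestScenarioAgreement:
    def test_identical_scenarios_full_agreement(self):
        m = np.array([[True, False], [True, True]])
        out = scenario_agreement([m, m, m])
        np.testing.assert_array_equal(out, np.where(m, 3, 0))

    def test_disjoint_scenarios_max_one(self):
        a = np.array([[True, False], [False, False]])
        b = np.array([[False, True], [False, False]])
        assert scenario_agreement([a, b]).max() == 1

    def test_equals_sum_of_indicator_rasters(self):
        rng = np.random.default_rng(4)
        sets = [rng.random((6, 6)) < 0.5 for _ in range(3)]
        np.testing.assert_array_equal(scenario_agreement(sets),
                                      sets[0].astype(int) + sets[1] + sets[2])

    def test_needs_two_scenarios(self):
        with pytest.raises(ValueError):
            scenario_agreement([np.zeros((2, 2), dtype=bool)])


def test_shift_report_covers_all_layers(toy_model_set, random_stack):
    present = project_niche(toy_model_set, random_stack)
    future = project_niche(toy_model_set, random_stack)
    report = ShiftReport.compute(present, future, "no-change")
    assert set(report.layers) == set(LAYERS)
    for layer, entry in report.layers.items():
        if entry["shift"] is not None:
            assert entry["shift"]["latitude"]["median"] == 0
            assert entry["lost_pct"] == 0 and entry["gained_pct"] == 0
    d = report.to_dict()
    assert d["scenario"] == "no-change"
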