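"""Season windows, peak anomalies, feature construction and the catalog."""

import numpy as np
import pytest

from gridveg import (
    ClimateCube,
    DEFAULT_WINDOWS,
    GridSpec,
    SeasonWindow,
    TimeAxis,
    anomaly_series,
    build_feature_catalog,
    monthly_max_composite,
    peak_anomaly,
    standardize,
    window_aggregate,
)
from gridveg.anomalies import FeatureSeries

WINDOWS = {w.name: w for w in DEFAULT_WINDOWS}


def monthly_cube(values, start_year, start_month=1, **kw):
    values = np.asarray(values, dtype=float)
    grid = GridSpec(values.shape[1], values.shape[2], 1.0)
    time = TimeAxis.monthly(start_year, start_month, values.shape[0])
    return ClimateCube(kw.get("product", "p"), kw.get("variable", "v"),
                       grid, time, values)


def series_cube(series, start_year, **kw):
    """Single-pixel monthly cube from a 1-D series."""
    return monthly_cube(np.asarray(series, float)[:, None, None], start_year, **kw)


class TestWindows:
    def test_hydrological_year_spans_jul_to_jun(self):
        w = WINDOWS["hydrological_year"]
        assert w.months[0] == (-1, 7) and w.months[-1] == (0, 6)
        assert len(w.months) == 12

    def test_window_month_sets(self):
        assert [m for _, m in WINDOWS["spring"].months] == [3, 4, 5]
        assert [m for _, m in WINDOWS["transition"].months] == [2, 3]
        assert [m for _, m in WINDOWS["winter_half"].months] == [11, 12, 1, 2, 3, 4]
        assert [m for _, m in WINDOWS["summer"].months] == [6, 7, 8]
        assert [m for _, m in WINDOWS["spring_summer"].months] == [3, 4, 5, 6, 7, 8]

    def test_window_aggregate_uses_previous_year_months(self):
        # 36 months 2004-2006, value = year*100 + month
        vals = [y * 100 + m for y in (2004, 2005, 2006) for m in range(1, 13)]
        cube = series_cube(vals, 2004)
        agg, valid = window_aggregate(cube, WINDOWS["hydrological_year"], 2005)
        expected = np.mean([2004 * 100 + m for m in range(7, 13)] +
                           [2005 * 100 + m for m in range(1, 7)])
        assert agg[0, 0] == pytest.approx(expected)
        agg_sp, _ = window_aggregate(cube, WINDOWS["spring"], 2005)
        assert agg_sp[0, 0] == pytest.approx(np.mean([200503, 200504, 200505]))

    def test_constant_field_aggregates_to_constant(self):
        cube = series_cube(np.full(36, 3.25), 2004)
        for w in DEFAULT_WINDOWS:
            agg, _ = window_aggregate(cube, w, 2005)
            assert agg[0, 0] == pytest.approx(3.25)

    def test_window_before_cube_start_raises(self):
        cube = series_cube(np.ones(24), 2004)
        with pytest.raises(ValueError):
            window_aggregate(cube, WINDOWS["hydrological_year"], 2004)


class TestMonthlyMaxComposite:
    def test_max_within_month(self):
        grid = GridSpec(1, 1, 1.0)
        time = TimeAxis("sixteen_day", ((2001, 7, 12), (2001, 7, 28)))
        cube = ClimateCube("m", "ndvi", grid, time,
                           np.array([0.3, 0.5])[:, None, None])
        out = monthly_max_composite(cube)
        assert out.values[0, 0, 0] == 0.5
        assert out.time.labels == ((2001, 7, 0),)

    def test_assignment_matches_date_bucket_oracle(self, rng):
        time = TimeAxis.sixteen_day(2001, 1)
        vals = rng.random((23, 2, 2))
        cube = ClimateCube("m", "ndvi", GridSpec(2, 2, 1.0), time, vals)
        out = monthly_max_composite(cube)
        assert len(out.time) == 12
        for i, (y, m, _) in enumerate(out.time.labels):
            idx = [t for t, (yy, mm, _) in enumerate(time.labels) if (yy, mm) == (y, m)]
            np.testing.assert_array_equal(out.values[i], vals[idx].max(axis=0))


class TestPeakAnomaly:
    def years_cube(self, peak_vals, n_years=3):
        """Monthly NDVI cube where Jul+Aug of year i equal peak_vals[i]."""
        n = n_years * 12
        vals = np.zeros((n, 1, 1))
        time = TimeAxis.monthly(2001, 1, n)
        for i, v in enumerate(peak_vals):
            vals[i * 12 + 6] = v
            vals[i * 12 + 7] = v
        return ClimateCube("m", "ndvi", GridSpec(1, 1, 1.0), time, vals)

    def test_constant_years_zero_anomaly(self):
        cube = self.years_cube([0.4, 0.4, 0.4])
        out = peak_anomaly(cube, (7, 8), [2001, 2002, 2003])
        np.testing.assert_allclose(out.anomaly, 0.0, atol=1e-12)

    def test_two_year_centering(self):
        cube = self.years_cube([0.2, 0.4], n_years=2)
        out = peak_anomaly(cube, (7, 8), [2001, 2002])
        np.testing.assert_allclose(out.anomaly, [-0.1, 0.1])

    def test_area_anomaly_equals_pixel_mean(self, rng):
        n = 36
        vals = rng.random((n, 3, 3))
        cube = ClimateCube("m", "ndvi", GridSpec(3, 3, 1.0),
                           TimeAxis.monthly(2001, 1, n), vals)
        out = peak_anomaly(cube, (7, 8), [2001, 2002, 2003])
        # oracle: direct averaging over pixels of per-pixel peak values
        peak = np.array([
            (vals[i * 12 + 6] + vals[i * 12 + 7]) / 2 for i in range(3)
        ]).reshape(3, 9)
        area = peak.mean(axis=1)
        np.testing.assert_allclose(out.anomaly, area - area.mean())
        np.testing.assert_allclose(out.pixel_anomaly.mean(axis=0), 0.0, atol=1e-12)

    def test_translation_invariance(self, rng):
        n = 36
        vals = rng.random((n, 2, 2))
        cube = ClimateCube("m", "ndvi", GridSpec(2, 2, 1.0),
                           TimeAxis.monthly(2001, 1, n), vals)
        shift = np.array([[1.0, 2.0], [3.0, 4.0]])
        shifted = ClimateCube("m", "ndvi", cube.grid, cube.time,
                              vals + shift[None, :, :])
        a = peak_anomaly(cube, (7, 8), [2001, 2002, 2003])
        b = peak_anomaly(shifted, (7, 8), [2001, 2002, 2003])
        np.testing.assert_allclose(a.anomaly, b.anomaly, atol=1e-12)
        np.testing.assert_allclose(a.pixel_anomaly, b.pixel_anomaly, atol=1e-12)

    def test_missing_peak_month_raises(self):
        cube = self.years_cube([0.2, 0.4], n_years=2)
        with pytest.raises(ValueError):
            peak_anomaly(cube, (7, 8), [2001, 2002, 2003])


class TestAnomalySeries:
    def test_centering_of_yearly_aggregates(self):
        # monthly values constant within each year: 2, 4, 6
        vals = np.repeat([2.0, 4.0, 6.0], 12)
        cube = series_cube(np.concatenate([np.full(12, 2.0), vals]), 2000)
        fs = anomaly_series(cube, WINDOWS["spring"], [2001, 2002, 2003])
        np.testing.assert_allclose(fs.anomaly, [-2.0, 0.0, 2.0])

    def test_two_year_pairwise_means_then_centering(self):
        # aggregates per year: 2000 -> 0, 2001..2003 -> 2, 4, 6
        vals = np.concatenate([np.full(12, 0.0), np.repeat([2.0, 4.0, 6.0], 12)])
        cube = series_cube(vals, 2000)
        fs = anomaly_series(cube, WINDOWS["spring"].as_two_year(), [2001, 2002, 2003])
        # pre-centering two-year values [1, 3, 5] -> centered [-2, 0, 2]
        np.testing.assert_allclose(fs.anomaly, [-2.0, 0.0, 2.0])

    def test_constant_years_all_zero(self):
        cube = series_cube(np.full(48, 7.0), 2000)
        fs = anomaly_series(cube, WINDOWS["summer"], [2001, 2002, 2003])
        np.testing.assert_allclose(fs.anomaly, 0.0)

    def test_too_few_years_raise(self):
        cube = series_cube(np.ones(24), 2000)
        with pytest.raises(ValueError):
            anomaly_series(cube, WINDOWS["spring"], [2001, 2002])

    def test_mean_zero_by_construction(self, rng):
        cube = monthly_cube(rng.standard_normal((60, 2, 2)), 2000)
        fs = anomaly_series(cube, WINDOWS["hydrological_year"],
                            [2001, 2002, 2003, 2004])
        assert abs(fs.anomaly.mean()) < 1e-12

    def test_correlation_invariant_to_mean_vs_sum(self, rng):
        # Pearson r is scale-invariant, so window mean vs window sum is moot
        cube = monthly_cube(rng.standard_normal((72, 2, 2)), 2000)
        y = rng.standard_normal(5)
        fs = anomaly_series(cube, WINDOWS["spring"], list(range(2001, 2006)))
        k = len(WINDOWS["spring"].months)
        r_mean = np.corrcoef(fs.anomaly, y)[0, 1]
        r_sum = np.corrcoef(fs.anomaly * k, y)[0, 1]
        assert r_mean == pytest.approx(r_sum)


class TestStandardize:
    def test_sd_convention(self):
        fs = FeatureSeries("p", "v", WINDOWS["spring"], [2001, 2002, 2003],
                           np.array([-2.0, 0.0, 2.0]))
        out = standardize(fs)
        np.testing.assert_allclose(out.anomaly, [-1.0, 0.0, 1.0])

    def test_unit_variance_series_unchanged(self, rng):
        a = rng.standard_normal(10)
        a = (a - a.mean())
        a = a / a.std(ddof=1)
        fs = FeatureSeries("p", "v", WINDOWS["spring"],
                           np.arange(2001, 2011), a)
        np.testing.assert_allclose(standardize(fs).anomaly, a)

    def test_constant_series_raises(self):
        fs = FeatureSeries("p", "v", WINDOWS["spring"], [2001, 2002, 2003],
                           np.zeros(3))
        with pytest.raises(ValueError):
            standardize(fs)


class TestCatalog:
    def test_plain_variable_12_features(self):
        cat = build_feature_catalog([("prod", ["precipitation"])])
        assert len(cat) == 12

    def test_snow_variable_excludes_summer_windows(self):
        cat = build_feature_catalog([("snow", ["ndsi"])])
        assert len(cat) == 8
        names = {d.window.name for d in cat}
        assert "summer" not in names and "spring_summer" not in names

    def test_empty_product_list(self):
        assert build_feature_catalog([]) == []

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            build_feature_catalog([("p", ["v"]), ("p", ["v"])])

    def test_hydrological_year_retained_for_snow(self):
        cat = build_feature_catalog([("snow", ["scd"])])
        assert any(d.window.name == "hydrological_year" for d in cat)
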