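import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from casecross.exposure import (
    DEFAULT_AQHI,
    aqhi_presentation_scale,
    average_stations,
    compute_aqhi,
    compute_iqr,
    daily_max_8h,
    daily_mean_24h,
    exposure_summary,
)


def hourly_frame(values, station="S1", pollutant="CO", day="2010-01-01"):
    ts = pd.date_range(day, periods=len(values), freq="h")
    return pd.DataFrame(
        {"station_id": station, "timestamp": ts, "pollutant": pollutant, "value": values}
    )


class TestDailyMean:
    def test_constant_day(self):
        out = daily_mean_24h(hourly_frame([0.3] * 24))
        assert out["value"].tolist() == [0.3]

    def test_arithmetic_mean(self):
        out = daily_mean_24h(hourly_frame([10.0] * 12 + [20.0] * 12), 0.75)
        assert out["value"].tolist() == [15.0]

    @pytest.mark.parametrize("n_hours", range(1, 25))
    def test_completeness_threshold_exhaustive(self, n_hours):
        # at the 0.75 default a day is valid iff it has >= 18 of 24 hours
        out = daily_mean_24h(hourly_frame([5.0] * n_hours), completeness_min=0.75)
        if n_hours / 24 >= 0.75:
            assert out["value"].tolist() == [5.0]
        else:
            assert out["value"].isna().all()

    def test_nan_hours_count_as_unavailable(self):
        values = [5.0] * 20 + [np.nan] * 4
        out = daily_mean_24h(hourly_frame(values), completeness_min=0.85)
        assert out["value"].isna().all()

    def test_duplicate_timestamps_rejected(self):
        frame = pd.concat([hourly_frame([1.0] * 3)] * 2)
        with pytest.raises(ValueError, match="duplicate"):
            daily_mean_24h(frame)

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            daily_mean_24h(hourly_frame([1.0]), completeness_min=0.0)


class TestDailyMax8h:
    def day_series(self, values, day="2010-06-01"):
        return pd.Series(values, index=pd.date_range(day, periods=len(values), freq="h"))

    def test_constant(self):
        assert daily_max_8h(self.day_series([40.0] * 24), "2010-06-01") == 40.0

    def test_hourly_ramp_brute_force(self):
        # ramp 0..23, windows confined to the day: best window is hours 16-23
        s = self.day_series(list(range(24)))
        got = daily_max_8h(s, "2010-06-01", window_policy="within_day")
        brute = max(np.mean(range(h, h + 8)) for h in range(17))
        assert got == brute == 19.5

    def test_isolated_block(self):
        vals = [0.0] * 8 + [100.0] * 8 + [0.0] * 8
        assert daily_max_8h(self.day_series(vals), "2010-06-01") == 100.0

    def test_cross_midnight_policy(self):
        # high values span 20:00-03:59; only the spillover policy sees them
        idx = pd.date_range("2010-06-01", periods=48, freq="h")
        vals = np.zeros(48)
        vals[20:28] = 80.0
        s = pd.Series(vals, index=idx)
        within = daily_max_8h(s, "2010-06-01", window_policy="within_day")
        spill = daily_max_8h(s, "2010-06-01", window_policy="cross_midnight")
        assert spill == 80.0
        brute_within = max(np.mean(vals[h : h + 8]) for h in range(17))
        assert within == pytest.approx(brute_within)

    def test_no_complete_window_is_missing(self):
        s = self.day_series([1.0] * 5)
        assert math.isnan(daily_max_8h(s, "2010-06-01"))

    def test_8h_max_at_least_daily_mean(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            vals = rng.gamma(2.0, 10.0, size=24)
            s = self.day_series(vals)
            assert daily_max_8h(s, "2010-06-01") >= vals.mean() - 1e-12


class TestAverageStations:
    def test_simple_mean(self):
        wide = pd.DataFrame({"a": [10.0], "b": [20.0], "c": [30.0]})
        assert average_stations(wide).tolist() == [20.0]

    def test_missing_station_still_averages(self):
        wide = pd.DataFrame({"a": [10.0], "b": [np.nan], "c": [30.0]})
        assert average_stations(wide, min_stations=2).tolist() == [20.0]

    def test_below_min_stations_is_missing(self):
        wide = pd.DataFrame({"a": [10.0], "b": [np.nan], "c": [np.nan]})
        assert average_stations(wide, min_stations=2).isna().all()

    def test_seven_stations(self):
        wide = pd.DataFrame({f"s{i}": [float(i)] for i in range(1, 8)})
        assert average_stations(wide).tolist() == [4.0]

    @settings(max_examples=50, derandomize=True)
    @given(st.permutations(list(range(5))))
    def test_permutation_invariant(self, perm):
        base = pd.DataFrame({f"s{i}": [float(v)] for i, v in enumerate([3, 1, 4, 1, 5])})
        shuffled = base[[f"s{i}" for i in perm]]
        assert average_stations(base).iloc[0] == average_stations(shuffled).iloc[0]


class TestAqhi:
    def test_zero_inputs(self):
        assert compute_aqhi(0.0, 0.0, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_formula_arbitrary_point(self):
        # (1000/10.4) * (e^{0.0537} - 1) evaluated independently
        expected = 1000 / 10.4 * (math.exp(0.000537 * 100) + 1 + 1 - 3)
        assert compute_aqhi(100.0, 0.0, 0.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(5.3046, abs=5e-5)

    def test_missing_input_propagates(self):
        assert math.isnan(compute_aqhi(np.nan, 10.0, 5.0))

    @settings(max_examples=100, derandomize=True)
    @given(
        st.floats(0, 100),
        st.floats(0, 100),
        st.floats(0, 100),
        st.floats(0.01, 5.0),
        st.sampled_from([0, 1, 2]),
    )
    def test_strictly_increasing_each_argument(self, o3, no2, pm, bump, which):
        args = [o3, no2, pm]
        base = compute_aqhi(*args)
        args[which] += bump
        assert compute_aqhi(*args) > base

    def test_near_linear_in_central_range(self):
        # over the central (mean +/- 1 IQR) operating region the index stays
        # within 0.05 units of its tangent plane at the all-months means
        m = np.array([23.5, 16.1, 8.9])
        iqr = np.array([12.8, 8.8, 6.5])
        c = np.array([DEFAULT_AQHI.c_o3, DEFAULT_AQHI.c_no2, DEFAULT_AQHI.c_pm25])
        f0 = compute_aqhi(*m)
        grad = DEFAULT_AQHI.scale * c * np.exp(c * m)
        grid = np.array(
            np.meshgrid(*[np.linspace(mi - w, mi + w, 9) for mi, w in zip(m, iqr)])
        ).reshape(3, -1).T
        exact = np.array([compute_aqhi(*row) for row in grid])
        taylor = f0 + (grid - m) @ grad
        assert np.max(np.abs(exact - taylor)) < 0.05

    def test_presentation_scale(self):
        assert aqhi_presentation_scale(2.996) == 3.0
        assert aqhi_presentation_scale(0.2) == 1.0  # floor at 1
        assert aqhi_presentation_scale(12.7) == 11.0  # the 10+ category
        assert math.isnan(aqhi_presentation_scale(np.nan))


class TestIqr:
    def test_1_to_100_linear_interpolation(self):
        assert compute_iqr(np.arange(1, 101)) == pytest.approx(49.5)

    def test_constant_series(self):
        assert compute_iqr([7.0] * 10) == 0.0

    def test_two_point_convention_pinned(self):
        # {0,10} padded to length 4; pins the linear-interpolation convention
        assert compute_iqr([0.0, 0.0, 10.0, 10.0]) == pytest.approx(10.0)
        with pytest.raises(ValueError):
            compute_iqr([0.0, 10.0])

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            compute_iqr([np.nan] * 10)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=4, max_size=60))
    def test_matches_brute_force_percentiles(self, values):
        # independent oracle: sort and interpolate order statistics directly
        v = np.sort(np.asarray(values))
        n = len(v)

        def pct(q):
            h = (n - 1) * q
            lo = int(np.floor(h))
            hi = min(lo + 1, n - 1)
            return v[lo] + (h - lo) * (v[hi] - v[lo])

        assert compute_iqr(values) == pytest.approx(pct(0.75) - pct(0.25), abs=1e-9)


def test_exposure_summary_shape():
    idx = pd.date_range("2010-01-01", periods=365, freq="D")
    rng = np.random.default_rng(1)
    daily = pd.DataFrame({"CO": rng.gamma(3, 0.1, 365), "NO2": rng.gamma(4, 4, 365)}, index=idx)
    season = pd.Series(np.where(idx.month.isin([10, 11, 12, 1, 2, 3]), "cold", "warm"), index=idx)
    out = exposure_summary(daily, season)
    assert set(out["season"]) == {"all", "cold", "warm"}
    assert (out["iqr"] >= 0).all()
    assert ((out["min"] <= out["mean"]) & (out["mean"] <= out["max"])).all()
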