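import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import casecross as cc
from casecross.design import (
    ICD_BLOCKS,
    StratumSpec,
    age_group,
    attach_lags,
    build_clusters,
    build_counts,
    classify_season,
    enumerate_strata,
    get_count_series,
    icd_block,
    season_labels,
)


@pytest.mark.parametrize(
    "date,season",
    [
        ("2010-10-15", "cold"),
        ("2010-04-01", "warm"),
        ("2010-03-31", "cold"),
        ("2010-09-30", "warm"),
        ("2010-01-01", "cold"),
    ],
)
def test_classify_season(date, season):
    assert classify_season(date) == season


def test_season_labels_vectorized_matches_scalar():
    idx = pd.date_range("2009-06-01", periods=400, freq="D")
    labels = season_labels(idx)
    assert all(labels[d] == classify_season(d) for d in idx[::13])


class TestIcdBlock:
    @pytest.mark.parametrize(
        "code,block,tag",
        [
            ("G43.1", "G40-G47", "migraine"),
            ("G47.9", "G40-G47", "sleep disorders"),
            ("G40", "G40-G47", "epilepsy"),
            ("G45", "G40-G47", "transient ischaemic attacks"),
            ("G00", "G00-G09", None),
            ("G99", "G90-G99", None),
            ("G56.0", "G50-G59", None),
        ],
    )
    def test_known_codes(self, code, block, tag):
        res = icd_block(code)
        assert res.block == block and res.tag == tag

    @pytest.mark.parametrize("code", ["H10", "A00", "G15", "G19", "G28", "G68"])
    def test_out_of_scope_codes(self, code):
        assert icd_block(code) is None

    @pytest.mark.parametrize("code", ["", "G", "4X", "G4X", 43, "G433X"])
    def test_malformed_rejected(self, code):
        with pytest.raises(ValueError):
            icd_block(code)

    def test_total_and_single_valued_on_chapter(self):
        # every G00-G99 code maps to at most one block, and exactly the
        # block whose printed range contains its numeric prefix
        for i in range(100):
            res = icd_block(f"G{i:02d}")
            containing = [b for b, (lo, hi) in ICD_BLOCKS.items() if lo <= i <= hi]
            assert len(containing) <= 1
            if containing:
                assert res.block == containing[0]
            else:
                assert res is None


class TestStrata:
    def test_exactly_18(self):
        strata = enumerate_strata()
        assert len(strata) == 18
        assert len(set(strata)) == 18

    def test_membership(self):
        assert StratumSpec(sex="F") in enumerate_strata()

    def test_never_age_and_season_together(self):
        for s in enumerate_strata():
            assert s.age == "all" or s.season == "all"
        with pytest.raises(ValueError):
            StratumSpec(sex="M", age="0-10", season="cold")

    def test_composition(self):
        strata = enumerate_strata()
        assert sum(1 for s in strata if s.age == "all" and s.season == "all") == 3
        assert sum(1 for s in strata if s.age != "all") == 9
        assert sum(1 for s in strata if s.season != "all") == 6


@pytest.mark.parametrize(
    "age,group", [(0, "0-10"), (10, "0-10"), (11, "11-60"), (60, "11-60"), (61, ">60"), (95, ">60")]
)
def test_age_group_boundaries(age, group):
    assert age_group(age) == group


class TestClusters:
    def test_single_day_degenerate(self):
        d = build_clusters("2010-05-03", "2010-05-03")
        assert d.n_days == 1 and d.n_clusters == 1
        assert d.cluster_sizes.tolist() == [1]

    def test_january_2015_enumeration(self):
        d = build_clusters("2015-01-01", "2015-01-31")
        assert d.n_clusters == 7
        assert d.cluster_sizes.sum() == 31
        assert set(d.cluster_sizes) <= {4, 5}

    def test_partition_is_exact(self):
        d = build_clusters("2004-04-01", "2006-07-15")
        assert d.cluster_sizes.sum() == d.n_days
        assert (d.days.groupby("cluster").size() == d.cluster_sizes).all()

    def test_clusters_never_cross_months(self):
        d = build_clusters("2004-04-01", "2006-07-15")
        per_cluster = d.days.groupby("cluster")[["year", "month", "weekday"]].nunique()
        assert (per_cluster == 1).all().all()

    def test_reversed_range_rejected(self):
        with pytest.raises(ValueError):
            build_clusters("2010-02-01", "2010-01-01")


class TestCounts:
    def test_empty_visits_all_zero(self):
        visits = pd.DataFrame(columns=["date", "icd10", "sex", "age"])
        counts = build_counts(visits, "2010-01-01", "2010-01-31")
        assert (counts["count"] == 0).all()
        # zero-filled complete index: one row per day/stratum/block
        assert len(counts) == 31 * 18 * 2

    def test_female_migraine_day(self):
        visits = pd.DataFrame(
            {
                "date": ["2010-01-05"] * 3,
                "icd10": ["G43.1", "G43", "G43.9"],
                "sex": ["F"] * 3,
                "age": [25, 40, 33],
            }
        )
        counts = build_counts(visits, "2010-01-01", "2010-01-31")
        day = pd.Timestamp("2010-01-05")
        for stratum in (StratumSpec(sex="F"), StratumSpec(sex="F", age="11-60")):
            s = get_count_series(counts, stratum, "G40-G47")
            assert s[day] == 3 and s.drop(day).sum() == 0
        assert get_count_series(counts, StratumSpec(sex="M"), "G40-G47").sum() == 0

    def test_sex_marginal_identity(self, small_dataset, small_counts):
        # M + F = all, exhaustively over strata cells and blocks
        for block in ("G00-G99", "G40-G47"):
            for age in ("all", "0-10", "11-60", ">60"):
                tot = get_count_series(small_counts, StratumSpec(age=age), block)
                m = get_count_series(small_counts, StratumSpec(sex="M", age=age), block)
                f = get_count_series(small_counts, StratumSpec(sex="F", age=age), block)
                assert ((m + f) == tot).all()

    def test_season_counts_sum_to_all(self, small_counts):
        tot = get_count_series(small_counts, StratumSpec(), "G00-G99")
        cold = get_count_series(small_counts, StratumSpec(season="cold"), "G00-G99")
        warm = get_count_series(small_counts, StratumSpec(season="warm"), "G00-G99")
        seasons = season_labels(tot.index)
        assert cold[(seasons == "cold").to_numpy()].sum() + warm[
            (seasons == "warm").to_numpy()
        ].sum() == tot.sum()
        # season strata still carry the full calendar; off-season days are zero
        assert cold[(seasons == "warm").to_numpy()].sum() == 0

    def test_block_counts_bounded_by_chapter(self, small_counts):
        tot = get_count_series(small_counts, StratumSpec(), "G00-G99").sum()
        g4047 = get_count_series(small_counts, StratumSpec(), "G40-G47").sum()
        assert 0 < g4047 <= tot


class TestAttachLags:
    def daily(self, n=30, seed=0):
        rng = np.random.default_rng(seed)
        idx = pd.date_range("2010-01-01", periods=n, freq="D")
        return pd.DataFrame(
            {
                "CO": rng.gamma(3, 0.1, n),
                "temperature": rng.normal(10, 8, n),
                "humidity": rng.uniform(40, 95, n),
            },
            index=idx,
        )

    def counts(self, n=30):
        idx = pd.date_range("2010-01-01", periods=n, freq="D")
        return pd.Series(np.arange(n), index=idx)

    def test_lag0_identity(self):
        daily = self.daily()
        out = attach_lags(self.counts(), daily, "CO", 0)
        assert np.array_equal(out["x"].to_numpy(), daily["CO"].to_numpy())

    def test_lag7_drops_leading_rows(self):
        daily = self.daily(10)
        out = attach_lags(self.counts(10), daily, "CO", 7)
        assert len(out) == 3
        assert out.attrs["n_dropped"] == 7

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(0, 14))
    def test_shift_matches_index_arithmetic(self, lag):
        daily = self.daily(60, seed=lag)
        out = attach_lags(self.counts(60), daily, "CO", lag)
        co = daily["CO"].to_numpy()
        # brute-force: row for day t carries exposure co[t - lag]
        expected = co[np.arange(lag, 60) - lag]
        assert np.array_equal(out["x"].to_numpy(), expected)

    def test_missing_lagged_exposure_dropped_and_logged(self):
        daily = self.daily(30)
        daily.loc[daily.index[4], "CO"] = np.nan
        out = attach_lags(self.counts(30), daily, "CO", 2)
        assert out.attrs["n_dropped"] == 3  # 2 boundary + 1 missing
        assert daily.index[6] not in out.index

    @pytest.mark.parametrize("lag", [-1, 15, 99])
    def test_lag_out_of_range(self, lag):
        with pytest.raises(ValueError):
            attach_lags(self.counts(), self.daily(), "CO", lag)
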