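"""Weekly weather aggregation, activity threshold, Spearman, abundance."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st

from aedes_diapause.core import MeteoDay, MeteoWeek
from aedes_diapause.datasets import (
    bas_rhin_biweekly_counts,
    reichstett_biweekly_counts,
)
from aedes_diapause.seasonality import (
    abundance_series,
    activity_threshold,
    spearman,
    weekly_meteo,
)

from conftest import make_record


def week_of_days(year, week, tmin, tmax, sun=300.0, rain=1.0, n_days=7):
    monday = dt.date.fromisocalendar(year, week, 1)
    return [
        MeteoDay(monday + dt.timedelta(days=i), tmin, tmax, sun, rain)
        for i in range(n_days)
    ]


def make_week(year, week, avtmin, avtmax):
    return MeteoWeek(
        iso_year=year, iso_week=week, avTmin=avtmin, avTmax=avtmax,
        minTmin=avtmin, minTmax=avtmax, maxTmin=avtmin, maxTmax=avtmax,
        avSun=0, cumulSun=0, avRain=0, cumulRain=0,
    )


class TestWeeklyMeteo:
    def test_constant_week_aggregates(self):
        (w,) = weekly_meteo(week_of_days(2019, 30, 4.0, 11.0))
        assert (w.avTmin, w.avTmax) == (4.0, 11.0)
        assert (w.minTmin, w.maxTmin) == (4.0, 4.0)
        assert (w.minTmax, w.maxTmax) == (11.0, 11.0)
        assert not w.partial

    def test_cumulative_identities_for_complete_weeks(self):
        (w,) = weekly_meteo(week_of_days(2019, 30, 4.0, 11.0, sun=120.0, rain=2.5))
        assert w.cumulSun == pytest.approx(7 * w.avSun)
        assert w.cumulRain == pytest.approx(7 * w.avRain)
        assert w.cumulRain == pytest.approx(17.5)

    def test_partial_week_flagged_not_dropped(self):
        (w,) = weekly_meteo(week_of_days(2019, 30, 4.0, 11.0, n_days=3))
        assert w.partial and w.n_days == 3

    def test_randomized_days_match_bruteforce(self):
        rng = np.random.default_rng(31)
        days = []
        d = dt.date(2019, 6, 3)
        for i in range(35):
            tmin = float(rng.normal(10, 3))
            days.append(
                MeteoDay(d + dt.timedelta(days=i), tmin, tmin + float(rng.gamma(2, 2)),
                         float(rng.uniform(0, 600)), float(rng.gamma(1, 3)))
            )
        rng.shuffle(days)
        weeks = {(w.iso_year, w.iso_week): w for w in weekly_meteo(days)}
        for (y, wk), w in weeks.items():
            sel = [x for x in days if x.date.isocalendar()[:2] == (y, wk)]
            assert w.avTmin == pytest.approx(np.mean([x.tmin_C for x in sel]))
            assert w.maxTmax == pytest.approx(max(x.tmax_C for x in sel))
            assert w.minTmin == pytest.approx(min(x.tmin_C for x in sel))
            assert w.cumulSun == pytest.approx(sum(x.sunshine_min for x in sel))
        # ordering invariants
        for w in weeks.values():
            assert w.minTmin <= w.avTmin <= w.maxTmin
            assert w.minTmax <= w.avTmax <= w.maxTmax


class TestActivityThreshold:
    def test_published_minima_give_7_5(self):
        meteo = [
            make_week(2019, 21, 12.0, 22.0),
            make_week(2019, 30, 15.0, 28.0),
            make_week(2019, 45, 4.0, 11.0),
        ]
        weeks = [(2019, w) for w in (21, 30, 45)]
        assert activity_threshold(weeks, meteo) == pytest.approx(7.5)

    def test_constant_temperature_is_identity(self):
        meteo = [make_week(2019, w, 9.0, 9.0) for w in range(20, 30)]
        weeks = [(2019, w) for w in range(20, 30)]
        assert activity_threshold(weeks, meteo) == pytest.approx(9.0)

    def test_only_egg_weeks_scanned(self):
        meteo = [make_week(2019, 20, -5.0, 0.0), make_week(2019, 30, 10.0, 20.0)]
        assert activity_threshold([(2019, 30)], meteo) == pytest.approx(15.0)

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(33)
        meteo = [
            make_week(2019, w, float(rng.normal(8, 4)), float(rng.normal(18, 4)))
            for w in range(20, 46)
        ]
        # fix ordering so MeteoWeek is internally consistent
        egg_weeks = [(2019, w) for w in range(22, 41)]
        got = activity_threshold(egg_weeks, meteo)
        sel = [m for m in meteo if 22 <= m.iso_week <= 40]
        expected = (min(m.avTmin for m in sel) + min(m.avTmax for m in sel)) / 2
        assert got == pytest.approx(expected)

    def test_no_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            activity_threshold([(2019, 30)], [make_week(2019, 20, 5, 15)])

    def test_no_egg_weeks_rejected(self):
        with pytest.raises(ValueError):
            activity_threshold([], [make_week(2019, 20, 5, 15)])


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
        up = spearman(x, [v**2 for v in x])
        down = spearman(x, [-v for v in x])
        assert up.rho == pytest.approx(1.0)
        assert down.rho == pytest.approx(-1.0)

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(35)
        for _ in range(20):
            x = rng.integers(0, 6, 15).astype(float)
            y = rng.integers(0, 6, 15).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            mine = spearman(x, y)
            ref = sps.spearmanr(x, y)
            assert mine.rho == pytest.approx(ref.statistic, abs=1e-12)
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_small_sample_exact_permutation(self):
        r = spearman([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert r.method == "exact permutation"
        # only the identity and the reversal reach |rho| = 1
        assert r.p_value == pytest.approx(2 / 120)

    def test_zero_variance_flagged(self):
        r = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert r.degenerate and np.isnan(r.rho)

    @given(
        st.lists(
            st.tuples(
                st.integers(-1000, 1000),
                st.floats(-100, 100, allow_nan=False),
            ),
            min_size=5,
            max_size=20,
            unique_by=lambda t: t[0],
        )
    )
    @settings(max_examples=40, deadline=None)
    def test_invariant_under_monotone_transform(self, pairs):
        # integer x keeps the transforms strictly monotone in float space
        x = [float(p[0]) for p in pairs]
        y = [p[1] for p in pairs]
        if np.ptp(y) == 0:
            return
        base = spearman(x, y)
        stretched = spearman([3.0 * v + 7.0 for v in x], y)
        expd = spearman([np.exp(v / 500.0) for v in x], y)
        assert base.rho == pytest.approx(stretched.rho, abs=1e-12)
        assert base.rho == pytest.approx(expd.rho, abs=1e-9)

    def test_unpaired_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [1, 2])


class TestAbundance:
    def test_reichstett_2019_total_matches_published(self):
        df = reichstett_biweekly_counts()
        s = abundance_series(df, bin_width=2, site="Reichstett")
        assert s.season_total[2019] == 25809
        assert s.season_total[2020] == 16859

    def test_bas_rhin_totals(self):
        s = abundance_series(bas_rhin_biweekly_counts(), bin_width=2)
        assert s.season_total == {2019: 5551, 2020: 8610}

    def test_binning_conserves_totals(self):
        df = reichstett_biweekly_counts()
        s1 = abundance_series(df, bin_width=1)
        s2 = abundance_series(df, bin_width=2)
        assert s1.season_total == s2.season_total

    def test_record_input_counts_every_egg(self, small_season):
        records, _, truth = small_season
        s = abundance_series(records, bin_width=2)
        assert s.season_total[2019] == sum(
            r["n_eggs"] for r in truth["realized"] if r["iso_year"] == 2019
        )

    def test_mean_sd_per_bin(self):
        df = pd.DataFrame(
            {"iso_year": [2019] * 4, "iso_week": [20, 21, 22, 23],
             "count": [10, 20, 30, 40]}
        )
        s = abundance_series(df, bin_width=2)
        assert [b.egg_count for b in s.bins] == [30, 70]
        assert s.mean_per_bin[2019] == pytest.approx(50.0)
        assert s.sd_per_bin[2019] == pytest.approx(np.std([30, 70], ddof=1))

    def test_bad_bin_width_rejected(self):
        with pytest.raises(ValueError):
            abundance_series(reichstett_biweekly_counts(), bin_width=3)
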