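import numpy as np
import pandas as pd
import pytest

from cgmetrics import indices as gv
from cgmetrics.io import GlucoseTrace

from oracles import (
    adrr_oracle,
    conga_oracle,
    lbgi_hbgi_oracle,
    mage_oracle,
    modd_oracle,
    risk_low_high,
)


def random_day(rng, n=None, missing=0.0):
    """Random tie-free glucose day, optionally with missing grid points."""
    n = n or int(rng.integers(10, 97))
    vals = rng.uniform(45, 320, n) + rng.uniform(0, 1e-3, n)
    if missing:
        mask = rng.random(n) < missing
        vals[mask] = np.nan
    return vals


class TestRangeFractions:
    @pytest.mark.parametrize(
        "day, lo, hi, expected",
        [
            ([100.0] * 8, 70, 180, (100.0, 0.0, 0.0)),
            ([60, 60, 100, 100], 70, 180, (50.0, 0.0, 50.0)),
            ([65, 90, 120, 190], 70, 110, (25.0, 50.0, 25.0)),
            ([70, 180], 70, 180, (100.0, 0.0, 0.0)),  # closed boundaries
        ],
    )
    def test_examples(self, day, lo, hi, expected):
        assert gv.range_fractions(day, lo, hi) == pytest.approx(expected)

    def test_empty_day_undefined(self):
        assert all(np.isnan(v) for v in gv.range_fractions([np.nan, np.nan]))

    def test_partition_sums_to_100(self, rng):
        for _ in range(200):
            day = random_day(rng, missing=0.2)
            if not np.isfinite(day).any():
                continue
            tir, tar, tbr = gv.range_fractions(day)
            assert tir + tar + tbr == pytest.approx(100.0, abs=1e-9)

    def test_tight_range_nested_in_standard(self, rng):
        for _ in range(50):
            day = random_day(rng)
            rtir = gv.range_fractions(day, 70, 110)[0]
            tir = gv.range_fractions(day, 70, 180)[0]
            assert rtir <= tir + 1e-12


class TestSdCv:
    def test_constant_day(self):
        assert gv.gv_sd_cv([100.0] * 10) == pytest.approx((0.0, 0.0))

    def test_two_point_closed_form(self):
        sd, cv = gv.gv_sd_cv([90.0, 110.0])
        assert sd == pytest.approx(np.sqrt(200))  # 14.142...
        assert cv == pytest.approx(np.sqrt(200))  # mean is 100

    def test_scaling(self, rng):
        day = random_day(rng, 30)
        sd, cv = gv.gv_sd_cv(day)
        sd2, cv2 = gv.gv_sd_cv(1.3 * day)
        assert sd2 == pytest.approx(1.3 * sd)
        assert cv2 == pytest.approx(cv)

    def test_single_reading_undefined(self):
        assert all(np.isnan(v) for v in gv.gv_sd_cv([100.0]))


class TestMage:
    def test_constant_day_is_zero(self):
        assert gv.mage([100.0] * 10) == 0.0

    def test_single_excursion(self):
        day = [100, 110, 125, 150, 125, 110, 100]
        # SD of the day is ~18, both swings have amplitude 50
        assert gv.mage(day) == pytest.approx(50.0)

    def test_five_point_series_matches_oracle(self):
        day = [100.0, 150.0, 100.0, 140.0, 100.0]
        assert gv.mage(day) == pytest.approx(mage_oracle(day))
        assert gv.mage(day) == pytest.approx(45.0)  # all four swings qualify

    def test_monotone_day_is_zero(self):
        assert gv.mage([100, 110, 120, 135, 160]) == 0.0

    def test_plateau_merged_into_one_excursion(self):
        day = [100, 120, 150, 150, 150, 120, 100]
        assert gv.mage(day) == pytest.approx(50.0)

    def test_translation_invariance(self, rng):
        day = random_day(rng, 50)
        assert gv.mage(day + 25) == pytest.approx(gv.mage(day))

    def test_oracle_equivalence_randomized(self, rng):
        for _ in range(200):
            day = random_day(rng)
            assert gv.mage(day) == pytest.approx(mage_oracle(day.tolist()))


class TestJIndex:
    @pytest.mark.parametrize("mean, sd, expected", [(100, 0, 10.0), (100, 20, 14.4)])
    def test_examples(self, mean, sd, expected):
        assert gv.j_index(mean, sd) == pytest.approx(expected)

    def test_strictly_increasing_in_each_argument(self):
        assert gv.j_index(110, 20) > gv.j_index(100, 20)
        assert gv.j_index(100, 25) > gv.j_index(100, 20)

    def test_domain(self):
        with pytest.raises(ValueError):
            gv.j_index(0, 10)


class TestRiskTransform:
    def test_root_near_112_5(self):
        rl, rh = gv.bg_risk(112.5)
        assert abs(gv.RISK_TRANSFORM.f(112.5)) < 1e-3
        assert rl < 1e-4 and rh < 1e-4

    def test_low_glucose_only_low_risk(self):
        rl, rh = gv.bg_risk(40)
        assert rl > 0 and rh == 0

    def test_high_glucose_only_high_risk(self):
        rl, rh = gv.bg_risk(400)
        assert rh > 0 and rl == 0

    def test_out_of_sensor_range_rejected(self):
        with pytest.raises(ValueError):
            gv.bg_risk(30)

    def test_f_strictly_increasing_on_sensor_range(self):
        bg = np.linspace(40, 500, 2000)
        assert (np.diff(gv.RISK_TRANSFORM.f(bg)) > 0).all()

    def test_branches_never_both_nonzero(self, rng):
        vals = rng.uniform(40, 500, 500)
        rl, rh = gv.RISK_TRANSFORM.low_high(vals)
        assert (rl * rh == 0).all()


class TestLbgiHbgi:
    def test_near_root_day_is_near_zero(self):
        lbgi, hbgi = gv.lbgi_hbgi([112.5] * 10)
        assert lbgi < 1e-4 and hbgi < 1e-4

    def test_all_low_readings_have_zero_hbgi(self):
        assert gv.lbgi_hbgi([80, 90, 100, 111])[1] == 0.0

    def test_oracle_equivalence(self, rng):
        for _ in range(50):
            day = random_day(rng)
            assert gv.lbgi_hbgi(day) == pytest.approx(lbgi_hbgi_oracle(day.tolist()))


class TestAdrr:
    def test_constant_near_root_subject(self):
        days = [[112.5] * 96] * 3
        assert gv.adrr(days) == pytest.approx(0.0, abs=1e-3)

    def test_single_day_equals_daily_risk_range(self):
        day = [60.0, 100.0, 250.0]
        expected = risk_low_high(60.0)[0] + risk_low_high(250.0)[1]
        assert gv.adrr([day]) == pytest.approx(expected)

    def test_oracle_equivalence_with_gaps(self, rng):
        for _ in range(60):
            days = [random_day(rng, 24, missing=0.2).tolist() for _ in range(3)]
            a, b = gv.adrr(days), adrr_oracle(days)
            assert a == pytest.approx(b, nan_ok=True)

    def test_no_valid_day_undefined(self):
        assert np.isnan(gv.adrr([[np.nan, np.nan]]))


class TestModd:
    def test_identical_days_zero(self):
        day = list(np.linspace(80, 160, 96))
        assert gv.modd([day, day]) == 0.0

    def test_constant_shift(self, rng):
        day = random_day(rng, 96)
        assert gv.modd([day, day + 10.0]) == pytest.approx(10.0)

    def test_oracle_equivalence_with_gaps(self, rng):
        for _ in range(60):
            days = [random_day(rng, 48, missing=0.25).tolist() for _ in range(3)]
            assert gv.modd(days) == pytest.approx(modd_oracle(days), nan_ok=True)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            gv.modd([[100, 100], [100, 100, 100]])


class TestConga:
    def test_constant_day_zero(self):
        assert gv.conga([100.0] * 96, 1.0, 15.0) == 0.0

    def test_lag_equal_to_period_vanishes(self):
        t = np.arange(192) * 15 / 60.0
        day = 120 + 30 * np.sin(2 * np.pi * t / 24.0)
        assert gv.conga(day, 24.0, 15.0) == pytest.approx(0.0, abs=1e-9)

    def test_twelve_point_fixture_matches_oracle(self, rng):
        day = random_day(rng, 12)
        assert gv.conga(day, 1.0, 15.0) == pytest.approx(conga_oracle(day.tolist(), 4))

    def test_oracle_equivalence_randomized(self, rng):
        for _ in range(100):
            day = random_day(rng, missing=0.2)
            lag_steps = int(rng.integers(1, 9))
            got = gv.conga(day, lag_steps * 15 / 60.0, 15.0)
            assert got == pytest.approx(conga_oracle(day.tolist(), lag_steps), nan_ok=True)

    def test_insufficient_span_undefined(self):
        assert np.isnan(gv.conga([100.0, 105.0], 1.0, 15.0))


class TestTranslationInvariance:
    def test_shift_moves_mean_only(self, rng):
        day = random_day(rng, 96)
        days = [random_day(rng, 96) for _ in range(3)]
        sd0, _ = gv.gv_sd_cv(day)
        sd1, _ = gv.gv_sd_cv(day + 30)
        assert sd1 == pytest.approx(sd0)
        assert gv.conga(day + 30, 1, 15) == pytest.approx(gv.conga(day, 1, 15))
        assert gv.modd([d + 30 for d in days]) == pytest.approx(gv.modd(days))
        assert np.mean(day + 30) == pytest.approx(np.mean(day) + 30)


class TestDailyTables:
    def test_daily_indices_structure_and_partition(self, small_study):
        daily = small_study["daily"]
        valid = daily[daily["valid"]]
        assert set(gv.DAILY_INDEX_COLUMNS) <= set(daily.columns)
        assert ((valid["tir"] + valid["tar"] + valid["tbr"] - 100).abs() < 1e-9).all()
        assert (valid["rtir"] <= valid["tir"] + 1e-12).all()
        assert valid["day_index"].between(2, 14).all()
        for col in ("mage", "lbgi", "hbgi", "conga_n"):
            assert (valid[col] >= 0).all()

    def test_cv_identity(self, small_study):
        valid = small_study["daily"].query("valid")
        np.testing.assert_allclose(
            valid["cv"], 100 * valid["sd"] / valid["mean_glucose"], rtol=1e-12
        )

    def test_subject_summary_aggregates(self, small_study):
        summary = small_study["summary"]
        assert (summary["adrr"] >= 0).all()
        assert (summary["modd"] >= 0).all()
        daily = small_study["daily"]
        sid = summary["subject_id"].iloc[0]
        mine = daily[(daily["subject_id"] == sid) & daily["valid"]]
        assert summary.set_index("subject_id").loc[sid, "mean_sd"] == pytest.approx(
            mine["sd"].mean()
        )

    def test_all_missing_day_markers_not_exceptions(self):
        idx = pd.date_range("2024-01-01", periods=2 * 96, freq="15min")
        vals = np.full(2 * 96, np.nan)
        vals[:96] = 100.0
        tr = GlucoseTrace("S1", pd.Series(vals, index=idx), interval_min=15.0)
        daily = gv.daily_indices(tr)
        # the all-missing day yields no row rather than an exception
        assert daily["day_index"].tolist() == [1]
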