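"""Thermal-index engine: formula oracles, AHL balance, QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from darkcut import climate
from darkcut.climate import (
    HliParams,
    accumulate_heat_load,
    compute_hli,
    compute_thi,
    estimate_bgt,
    index_series,
    qc_and_resample,
)


def ahl_oracle(hli, lower=77.0, upper=86.0, m=4):
    """Independent scalar-loop trace of the heat-load balance."""
    bal, out = 0.0, []
    for h in hli:
        if h > upper:
            bal += (h - upper) / m
        elif h < lower:
            bal += (h - lower) / m
        bal = max(bal, 0.0)
        out.append(bal)
    return out


class TestBgt:
    @pytest.mark.parametrize(
        "ta,sr,expected",
        [(25.0, 0.0, 23.50), (0.0, 0.0, 3.5)],
    )
    def test_no_radiation_values(self, ta, sr, expected):
        assert estimate_bgt(ta, sr) == pytest.approx(expected, abs=1e-6)

    def test_radiation_heats_the_globe(self):
        srs = np.array([0.0, 100.0, 400.0, 800.0, 1200.0])
        vals = estimate_bgt(np.full_like(srs, 25.0), srs)
        assert np.all(np.diff(vals) > 0)

    def test_subzero_uses_odd_square_root_extension(self):
        # continuous through 0 and defined for winter nights
        assert estimate_bgt(-5.0, 0.0) == pytest.approx(
            1.33 * -5 + 2.65 * np.sqrt(5) + 3.5
        )

    def test_implausible_temperature_rejected(self):
        with pytest.raises(ValueError):
            estimate_bgt(-80.0, 0.0)


class TestThi:
    def test_hand_oracle(self):
        assert compute_thi(25.0, 50.0) == pytest.approx(71.7, abs=1e-6)
        assert compute_thi(0.0, 0.0) == pytest.approx(46.4, abs=1e-6)

    @given(rh1=st.floats(0, 100), rh2=st.floats(0, 100))
    @settings(max_examples=50, derandomize=True)
    def test_humidity_neutral_at_14_4(self, rh1, rh2):
        assert compute_thi(14.4, rh1) == pytest.approx(
            compute_thi(14.4, rh2), abs=1e-9
        )

    def test_rh_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            compute_thi(20.0, 130.0)


class TestHli:
    def test_hand_oracles(self):
        assert compute_hli(30.0, 50.0, 2.0) == pytest.approx(
            8.62 + 19 + 46.5 - 1 + np.exp(0.4), abs=1e-6
        )
        assert compute_hli(20.0, 40.0, 1.0) == pytest.approx(46.86, abs=1e-6)

    def test_high_wind_limit_on_hot_branch(self):
        assert compute_hli(30.0, 50.0, 20.0) == pytest.approx(
            8.62 + 19 + 46.5 - 10, abs=1e-7
        )

    def test_boundary_bgt_uses_linear_branch(self):
        linear = 10.66 + 0.28 * 50 + 1.3 * 25 - 1.0
        assert compute_hli(25.0, 50.0, 1.0) == pytest.approx(linear)

    @given(
        bgt=st.floats(-5, 45),
        rh=st.floats(1, 99),
        ws=st.floats(0.1, 15),
    )
    @settings(max_examples=100, derandomize=True)
    def test_branch_monotonicity(self, bgt, rh, ws):
        h = compute_hli(bgt, rh, ws)
        assert compute_hli(bgt, min(rh + 0.5, 100), ws) > h
        assert compute_hli(bgt, rh, ws + 0.5) < h
        # BGT step chosen to stay on one side of the branch switch
        step = 0.01
        if not (bgt <= 25.0 < bgt + step):
            assert compute_hli(bgt + step, rh, ws) > h


class TestAhl:
    def test_constant_exceedance_integrates_to_degree_hours(self):
        out = accumulate_heat_load([90.0] * 4, HliParams())
        assert out[-1] == pytest.approx(4.0)

    def test_step_trace(self):
        out = accumulate_heat_load([90, 90, 70, 70], HliParams())
        assert out == pytest.approx([1.0, 2.0, 0.25, 0.0])

    def test_cool_series_stays_zero(self):
        rng = np.random.default_rng(0)
        hli = rng.uniform(30, 76.9, 500)
        assert np.all(accumulate_heat_load(hli) == 0.0)

    def test_empty_series(self):
        assert len(accumulate_heat_load([])) == 0

    def test_matches_scalar_loop_oracle_on_many_series(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = rng.integers(1, 120)
            hli = rng.uniform(40, 110, n)
            got = accumulate_heat_load(hli)
            want = ahl_oracle(hli)
            np.testing.assert_allclose(got, want, atol=1e-10)

    @given(st.lists(st.floats(30, 120), min_size=1, max_size=100))
    @settings(max_examples=100, derandomize=True)
    def test_nonnegative_and_zero_law(self, hli):
        out = accumulate_heat_load(hli)
        assert np.all(out >= 0)
        if max(hli) <= 86.0:
            assert out[-1] == 0.0


class TestIndexSeries:
    def test_composes_the_elementwise_formulas(self):
        obs = pd.DataFrame({
            "timestamp": [pd.Timestamp("2018-01-01 12:00")],
            "ta": [25.0], "rh": [50.0], "sr": [0.0], "ws": [2.0],
            "rain": [0.0],
        })
        out = index_series(obs)
        assert out["thi"].iloc[0] == pytest.approx(71.7)
        assert out["bgt"].iloc[0] == pytest.approx(23.50, abs=1e-6)
        # BGT < 25 -> linear branch
        assert out["hli"].iloc[0] == pytest.approx(
            10.66 + 0.28 * 50 + 1.3 * 23.50 - 2.0
        )

    def test_empty_input(self):
        empty = pd.DataFrame(columns=climate.WEATHER_COLUMNS)
        out = index_series(empty)
        assert len(out) == 0

    def test_cool_night_accumulates_nothing(self):
        ts = pd.date_range("2018-06-01", periods=96, freq="15min")
        obs = pd.DataFrame({
            "timestamp": ts, "ta": 5.0, "rh": 60.0, "sr": 0.0,
            "ws": 1.0, "rain": 0.0,
        })
        out = index_series(obs)
        assert (out["ahl"] == 0).all()

    def test_non_monotone_timestamps_rejected(self):
        obs = pd.DataFrame({
            "timestamp": pd.to_datetime(
                ["2018-01-01 00:15", "2018-01-01 00:00"]
            ),
            "ta": 20.0, "rh": 50.0, "sr": 0.0, "ws": 1.0, "rain": 0.0,
        })
        with pytest.raises(ValueError, match="increasing"):
            index_series(obs)


class TestQc:
    def _frame(self, **overrides):
        ts = pd.date_range("2018-01-01", periods=8, freq="15min")
        base = {"ta": 20.0, "rh": 50.0, "sr": 100.0, "ws": 2.0, "rain": 0.0}
        base.update(overrides)
        return pd.DataFrame({"timestamp": ts, **base})

    def test_midpoint_interpolation(self):
        df = self._frame()
        df.loc[3, "ta"] = np.nan
        df.loc[2, "ta"] = 20.0
        df.loc[4, "ta"] = 22.0
        clean, rep = qc_and_resample(df)
        assert clean["ta"].iloc[3] == pytest.approx(21.0)
        assert rep.interpolated["ta"] == 1

    def test_out_of_range_masked_and_reported(self):
        df = self._frame()
        df.loc[5, "rh"] = 130.0
        clean, rep = qc_and_resample(df)
        assert rep.masked["rh"] == 1
        # masked then interpolated back from neighbours
        assert clean["rh"].iloc[5] == pytest.approx(50.0)

    def test_long_gap_left_missing(self):
        ts1 = pd.date_range("2018-01-01", periods=4, freq="15min")
        ts2 = pd.date_range("2018-01-04", periods=4, freq="15min")
        df = pd.DataFrame({
            "timestamp": ts1.append(ts2),
            "ta": 20.0, "rh": 50.0, "sr": 0.0, "ws": 1.0, "rain": 0.0,
        })
        clean, rep = qc_and_resample(df, max_gap=6.0)
        assert rep.left_missing["ta"] > 0
        assert len(rep.gaps) == 1
        assert clean["ta"].isna().sum() > 0

    def test_rain_gap_zero_filled(self):
        df = self._frame()
        df.loc[3, "rain"] = np.nan
        clean, _ = qc_and_resample(df)
        assert clean["rain"].iloc[3] == 0.0
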