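import dataclasses
import io

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import leafwue.forcing as fo
from leafwue.errors import DomainError, FormatError, ParameterError, RangeError


class TestIdealLight:
    @pytest.mark.parametrize(
        "im, ia, offset, expected",
        [
            (237.0, 137.02, 0.0, 237.0 - 137.02),      # minimum at the origin
            (237.0, 137.02, 3600.0, 237.0 + 137.02),   # maximum half a cycle later
            (139.0, 133.435, 0.0, 5.565),              # cloudy-day trough
        ],
    )
    def test_extremes(self, im, ia, offset, expected):
        p = fo.IdealDayParams(im=im, ia=ia, period=3600.0)
        assert fo.ideal_light(p.phase_origin + offset, p) == pytest.approx(expected)

    def test_zero_outside_photoperiod(self):
        p = fo.IdealDayParams(im=200.0, ia=100.0)
        assert fo.ideal_light(p.day_start - 1.0, p) == 0.0
        assert fo.ideal_light(p.day_end + 1.0, p) == 0.0

    def test_clamped_at_zero_when_amplitude_exceeds_mean(self):
        p = fo.IdealDayParams(im=50.0, ia=120.0)
        t = np.linspace(p.day_start, p.day_end, 2001)
        assert np.all(fo.ideal_light(t, p) >= 0.0)

    def test_nonpositive_period_rejected(self):
        with pytest.raises(ParameterError):
            fo.IdealDayParams(im=200.0, ia=100.0, period=0.0)

    @pytest.mark.parametrize("period", [1800.0, 2700.0, 3600.0])
    def test_photoperiod_integral_is_mean_times_daylength(self, period):
        """When the photoperiod holds whole half-cycles the cosine
        integrates away and the light integral equals Im * day length."""
        p = fo.IdealDayParams(im=237.0, ia=137.02, period=period)
        t = np.linspace(p.day_start, p.day_end, 540001)
        integral = np.trapezoid(fo.ideal_light(t, p), t)
        expected = p.im * (p.day_end - p.day_start)
        assert integral == pytest.approx(expected, rel=1e-7)


class TestIdealTemperature:
    def test_minimum_lagged_behind_light_minimum(self):
        p = fo.IdealDayParams(im=200.0, ia=100.0, lag=1800.0)
        assert fo.ideal_temperature(p.phase_origin + p.lag, p) == pytest.approx(
            p.tm - p.ta_amp)

    def test_constant_when_amplitude_zero(self):
        p = fo.IdealDayParams(im=200.0, ia=100.0, ta_amp=0.0, lag=0.0)
        t = np.linspace(p.day_start, p.day_end, 100)
        assert np.allclose(fo.ideal_temperature(t, p), p.tm)

    def test_lag_shifts_minimum_exactly(self):
        p = fo.IdealDayParams(im=200.0, ia=100.0, lag=1800.0, period=3600.0)
        light_min = p.phase_origin + 2 * p.period  # an interior light minimum
        t = np.linspace(light_min, light_min + p.period, 20001)
        temps = fo.ideal_temperature(t, p)
        t_min = t[np.argmin(temps)]
        assert t_min - light_min == pytest.approx(p.lag, abs=1.0)


class TestHumidityFromTemperature:
    def test_printed_evaluation(self):
        assert fo.hr_from_ta(293.16) == pytest.approx(85.95, abs=0.01)

    def test_clamped_at_100_below_threshold(self):
        assert fo.hr_from_ta(291.24) == 100.0

    def test_limit_to_zero(self):
        assert fo.hr_from_ta(1000.0) < 2.0

    def test_domain_error_at_asymptote(self):
        with pytest.raises(DomainError):
            fo.hr_from_ta(273.16 + 6.3458)

    @given(st.floats(min_value=292.0, max_value=330.0),
           st.floats(min_value=0.01, max_value=10.0))
    def test_strictly_decreasing(self, ta, dta):
        lo, hi = fo.hr_from_ta(ta), fo.hr_from_ta(ta + dta)
        assert hi < lo or (lo == 100.0 and hi <= 100.0)


class TestClimateCsv:
    def make_csv(self, text: str) -> io.StringIO:
        return io.StringIO(text)

    def test_well_formed_roundtrip(self):
        series = fo.read_climate_csv(self.make_csv(
            "time,ppfd,ta,hr\n06:00:00,0,22,80\n06:10:00,50,22.5,78\n06:20:00,100,23,75\n"
        ))
        assert len(series.records) == 3
        assert series.t[0] == 6 * 3600.0
        assert np.all(np.diff(series.t) > 0)
        # degC auto-detected and converted
        assert series.ta[0] == pytest.approx(22 + 273.16)
        assert np.all(series.ca == 380.0)

    def test_kelvin_not_converted(self):
        series = fo.read_climate_csv(self.make_csv(
            "time,ppfd,ta,hr\n0,0,295.15,80\n60,10,295.2,79\n"))
        assert series.ta[0] == pytest.approx(295.15)

    @pytest.mark.parametrize(
        "text",
        [
            "time,ppfd,ta,hr\n0,0,22,120\n60,0,22,80\n",     # hr out of range
            "time,ppfd,ta\n0,0,22\n60,0,22\n",               # missing column
            "time,ppfd,ta,hr\n0,0,22,80\n0,0,22,80\n",       # duplicate time
            "time,ppfd,ta,hr\n0,xx,22,80\n60,0,22,80\n",     # unparseable row
            "time,ppfd,ta,hr\n0,-5,22,80\n60,0,22,80\n",     # negative ppfd
        ],
    )
    def test_malformed_rejected(self, text):
        with pytest.raises(FormatError):
            fo.read_climate_csv(self.make_csv(text))


class TestInterpolation:
    def test_exact_at_sample_points(self, tiny_series):
        rec = tiny_series.at(600.0)
        assert rec.ppfd == 200.0
        assert rec.ta == 295.15
        assert rec.hr == 70.0

    def test_linear_midpoint(self, tiny_series):
        assert tiny_series.at(300.0).ppfd == pytest.approx(150.0)

    def test_out_of_span(self, tiny_series):
        with pytest.raises(RangeError):
            tiny_series.at(1201.0)

    @given(st.floats(min_value=0.0, max_value=1200.0))
    def test_bounded_by_neighbours(self, t):
        series = fo.ClimateSeries(
            t=np.array([0.0, 600.0, 1200.0]),
            ppfd=np.array([100.0, 200.0, 150.0]),
            ta=np.array([293.15, 295.15, 294.15]),
            hr=np.array([80.0, 70.0, 75.0]),
            ca=np.array([380.0, 380.0, 380.0]),
        )
        rec = series.at(t)
        idx = np.searchsorted(series.t, t)
        lo = max(idx - 1, 0)
        hi = min(idx, len(series.t) - 1)
        pair = sorted((series.ppfd[lo], series.ppfd[hi]))
        assert pair[0] - 1e-9 <= rec.ppfd <= pair[1] + 1e-9


class TestMakeIdealDay:
    def test_mean_light_matches_scenario_mean(self):
        series = fo.make_ideal_day(fo.CLOUDY)
        mean = np.trapezoid(series.ppfd, series.t) / (series.t[-1] - series.t[0])
        assert float(mean) == pytest.approx(139.0, rel=1e-6)

    def test_humidity_consistent_with_temperature(self):
        series = fo.make_ideal_day(fo.SUNNY)
        expected = fo.hr_from_ta(series.ta)
        assert np.allclose(series.hr, expected)

    def test_constant_scenario(self):
        p = dataclasses.replace(fo.SUNNY, ia=0.0, ta_amp=0.0)
        series = fo.make_ideal_day(p)
        assert np.allclose(series.ppfd, p.im)
        assert np.allclose(series.ta, p.tm)
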