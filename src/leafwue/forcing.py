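"""Environmental forcing: measured-style climate CSV files and synthetic
"ideal day" scenarios.

An ideal day drives the leaf with a sinusoidally fluctuating light intensity

    I(t) = Im + Ia * cos(pi * (t - t0) / p - pi)

over a 15-h photoperiod, so that light starts at its minimum (Im - Ia) at
t0 and oscillates with period 2p between Im - Ia and Im + Ia while its
photoperiod mean stays at Im.  Air temperature follows the same shape,
delayed by a fixed lag (default 30 min), and relative humidity is derived
from temperature through a hyperbolic decay fitted to greenhouse data:

    hr(Ta) = 1173.613 / (Ta[degC] - 6.3458),  clamped at 100 %.
"""
from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DomainError, FormatError, ParameterError, RangeError

__all__ = [
    "EnvRecord",
    "IdealDayParams",
    "SUNNY",
    "CLOUDY",
    "ideal_light",
    "ideal_temperature",
    "hr_from_ta",
    "ClimateSeries",
    "read_climate_csv",
    "make_ideal_day",
]

log = logging.getLogger(__name__)

T_ZERO_C = 273.16  # K at 0 degC as used by the psychrometric relations

# humidity--temperature hyperbola (fitted to greenhouse records)
HR_SCALE = 1173.613   # % degC
HR_OFFSET = 6.3458    # degC; relation valid only above this temperature

DEFAULT_CA = 380.0  # umol mol-1

SECONDS_PER_HOUR = 3600.0


@dataclass(frozen=True)
class EnvRecord:
    """One timestamped sample of the forcing environment."""

    t: float      # seconds since midnight
    ppfd: float   # umol photon m-2 s-1
    ta: float     # air temperature, K
    hr: float     # relative humidity, % in (0, 100]
    ca: float = DEFAULT_CA  # ambient CO2, umol mol-1

    def validate(self) -> "EnvRecord":
        if self.ppfd < 0:
            raise FormatError(f"ppfd must be >= 0, got {self.ppfd} at t={self.t}")
        if self.ta <= T_ZERO_C - 50.0:
            raise FormatError(f"implausible air temperature {self.ta} K at t={self.t}")
        if not (0.0 < self.hr <= 100.0):
            raise FormatError(f"hr must be in (0, 100], got {self.hr} at t={self.t}")
        if self.ca <= 0:
            raise FormatError(f"ca must be positive, got {self.ca} at t={self.t}")
        return self


@dataclass(frozen=True)
class IdealDayParams:
    """Sinusoidal light/temperature scenario over a 15-h photoperiod.

    ``im``/``ia`` are the photoperiod-mean light and its amplitude; the
    published calibration pairs are 237/137.02 (sunny) and 139/133.435
    (cloudy) umol photon m-2 s-1.  ``period`` is the half-cycle parameter p
    of the sinusoid (the full fluctuation cycle is 2p); the default 3600 s
    (a 2-h cycle) fits fifteen half-cycles into the 15-h photoperiod, so
    the photoperiod-mean light is exactly ``im`` and the day's light
    integral matches a constant-light day at ``im`` -- the matched-integral
    construction.  The temperature mean ``tm`` and amplitude ``ta_amp`` are
    explicit scenario choices (the calibration data never constrained
    them); defaults are 295.15 K and 4 K.
    """

    im: float                    # mean daytime PPFD, umol m-2 s-1
    ia: float                    # PPFD amplitude, umol m-2 s-1
    period: float = 3600.0       # half-cycle parameter p, s (full cycle = 2p)
    day_start: float = 6 * SECONDS_PER_HOUR
    day_end: float = 21 * SECONDS_PER_HOUR
    t0: float | None = None      # phase origin; defaults to day_start (minimum)
    tm: float = 295.15           # mean daytime air temperature, K
    ta_amp: float = 4.0          # temperature amplitude, K
    lag: float = 1800.0          # light -> temperature lag, s

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ParameterError(f"fluctuation period must be positive, got {self.period}")
        if self.day_end <= self.day_start:
            raise ParameterError("day_end must exceed day_start")
        if self.ia > self.im:
            log.warning(
                "light amplitude %.3f exceeds mean %.3f; negative lobes clamped at 0",
                self.ia, self.im,
            )

    @property
    def phase_origin(self) -> float:
        return self.day_start if self.t0 is None else self.t0


SUNNY = IdealDayParams(im=237.0, ia=137.02)
CLOUDY = IdealDayParams(im=139.0, ia=133.435)


def _sinusoid(t, mean: float, amp: float, t0: float, period: float):
    return mean + amp * np.cos(np.pi * (np.asarray(t, dtype=float) - t0) / period - np.pi)


def ideal_light(t, params: IdealDayParams):
    """PPFD of the ideal-day sinusoid at time ``t`` (s since midnight).

    Zero outside the photoperiod; clamped at zero from below.  Accepts
    scalars or arrays.
    """
    t = np.asarray(t, dtype=float)
    val = _sinusoid(t, params.im, params.ia, params.phase_origin, params.period)
    val = np.clip(val, 0.0, None)
    inside = (t >= params.day_start) & (t <= params.day_end)
    out = np.where(inside, val, 0.0)
    return float(out) if out.ndim == 0 else out


def ideal_temperature(t, params: IdealDayParams):
    """Air temperature (K) of the ideal day: the light sinusoid shape with
    mean ``tm``, amplitude ``ta_amp``, and phase delayed by ``lag``.

    Outside the (lag-shifted) photoperiod the night value ``tm - ta_amp``
    (the daytime minimum) is returned, keeping the series continuous.
    """
    t = np.asarray(t, dtype=float)
    val = _sinusoid(t, params.tm, params.ta_amp, params.phase_origin + params.lag,
                    params.period)
    inside = (t >= params.day_start + params.lag) & (t <= params.day_end + params.lag)
    out = np.where(inside, val, params.tm - params.ta_amp)
    return float(out) if out.ndim == 0 else out


def hr_from_ta(ta):
    """Relative humidity (%) from air temperature (K), hyperbolic decay.

    Valid only for temperatures above the ``HR_OFFSET`` asymptote
    (6.3458 degC); clamped at 100 % (the raw hyperbola exceeds 100 below
    about 18.08 degC).
    """
    ta = np.asarray(ta, dtype=float)
    tc = ta - T_ZERO_C
    if np.any(tc <= HR_OFFSET):
        raise DomainError(
            f"humidity relation undefined at or below {HR_OFFSET + T_ZERO_C:.4f} K"
        )
    out = np.minimum(HR_SCALE / (tc - HR_OFFSET), 100.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class ClimateSeries:
    """A time-ordered forcing series with linear interpolation between samples."""

    t: np.ndarray      # s since midnight, strictly increasing
    ppfd: np.ndarray
    ta: np.ndarray     # K
    hr: np.ndarray     # %
    ca: np.ndarray     # umol mol-1
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        for name in ("ppfd", "ta", "hr", "ca"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.t.shape:
                raise FormatError(f"column {name!r} length mismatch")
            setattr(self, name, arr)
        if self.t.size < 2:
            raise FormatError("a climate series needs at least two samples")
        dtv = np.diff(self.t)
        if np.any(dtv <= 0):
            bad = int(np.argmax(dtv <= 0)) + 1
            raise FormatError(f"timestamps not strictly increasing at row {bad}")
        for rec in (self.records[0], self.records[-1]):
            rec.validate()
        if np.any(self.ppfd < 0) or np.any((self.hr <= 0) | (self.hr > 100)):
            raise FormatError("series violates ppfd >= 0 or 0 < hr <= 100")

    @property
    def span(self) -> tuple[float, float]:
        return float(self.t[0]), float(self.t[-1])

    @property
    def records(self) -> list[EnvRecord]:
        return [
            EnvRecord(float(t), float(p), float(a), float(h), float(c))
            for t, p, a, h, c in zip(self.t, self.ppfd, self.ta, self.hr, self.ca)
        ]

    def at(self, t: float) -> EnvRecord:
        """Linearly interpolated environment at time ``t`` (s)."""
        lo, hi = self.span
        if not (lo <= t <= hi):
            raise RangeError(f"t={t} outside forcing span [{lo}, {hi}]")
        return EnvRecord(
            t=float(t),
            ppfd=float(np.interp(t, self.t, self.ppfd)),
            ta=float(np.interp(t, self.t, self.ta)),
            hr=float(np.interp(t, self.t, self.hr)),
            ca=float(np.interp(t, self.t, self.ca)),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.t, "ppfd": self.ppfd, "ta": self.ta,
             "hr": self.hr, "ca": self.ca}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _parse_time(value, row: int) -> float:
    """Accept seconds since midnight or HH:MM[:SS]."""
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    text = str(value).strip()
    if ":" in text:
        parts = text.split(":")
        if len(parts) not in (2, 3) or not all(p.strip() for p in parts):
            raise FormatError(f"row {row}: cannot parse time {value!r}")
        try:
            nums = [float(p) for p in parts]
        except ValueError as exc:
            raise FormatError(f"row {row}: cannot parse time {value!r}") from exc
        h, m = nums[0], nums[1]
        s = nums[2] if len(nums) == 3 else 0.0
        return h * 3600.0 + m * 60.0 + s
    try:
        return float(text)
    except ValueError as exc:
        raise FormatError(f"row {row}: cannot parse time {value!r}") from exc


def read_climate_csv(path: str | Path | io.IOBase) -> ClimateSeries:
    """Read a climate CSV with columns ``time,ppfd,ta,hr[,ca]``.

    ``time`` may be seconds since midnight or ``HH:MM:SS``.  Temperature is
    auto-detected as degC vs K by magnitude (values below 150 are treated as
    degC and converted; the conversion is logged).  Rows must be in strictly
    increasing time order with no duplicates.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"cannot read climate CSV: {exc}") from exc
    df.columns = [str(c).strip().lower() for c in df.columns]
    required = ("time", "ppfd", "ta", "hr")
    for col in required:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    times = np.array([_parse_time(v, i) for i, v in enumerate(df["time"], start=1)])
    for col in ("ppfd", "ta", "hr"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.isna().idxmax()) + 1
            raise FormatError(f"row {row}: unparseable value in column {col!r}")
        df[col] = vals
    ta = df["ta"].to_numpy(dtype=float)
    if np.nanmax(ta) < 150.0:
        log.info("temperature column interpreted as degC; converting to K")
        ta = ta + T_ZERO_C
    if "ca" in df.columns:
        ca = pd.to_numeric(df["ca"], errors="coerce")
        if ca.isna().any():
            row = int(ca.isna().idxmax()) + 1
            raise FormatError(f"row {row}: unparseable value in column 'ca'")
        ca = ca.to_numpy(dtype=float)
    else:
        ca = np.full_like(ta, DEFAULT_CA)
    order = np.argsort(times, kind="stable")
    times, ta, ca = times[order], ta[order], ca[order]
    ppfd = df["ppfd"].to_numpy(dtype=float)[order]
    hr = df["hr"].to_numpy(dtype=float)[order]
    dup = np.nonzero(np.diff(times) == 0)[0]
    if dup.size:
        raise FormatError(f"duplicate timestamp at row {int(dup[0]) + 2}")
    bad_hr = np.nonzero((hr <= 0) | (hr > 100))[0]
    if bad_hr.size:
        raise FormatError(f"row {int(bad_hr[0]) + 1}: hr outside (0, 100]")
    bad_p = np.nonzero(ppfd < 0)[0]
    if bad_p.size:
        raise FormatError(f"row {int(bad_p[0]) + 1}: negative ppfd")
    return ClimateSeries(t=times, ppfd=ppfd, ta=ta, hr=hr, ca=ca,
                         meta={"source": str(path)})


def make_ideal_day(
    params: IdealDayParams,
    sample_dt: float = 60.0,
    ca: float = DEFAULT_CA,
) -> ClimateSeries:
    """Sample an ideal-day scenario into a ClimateSeries.

    Samples every ``sample_dt`` seconds from day_start to day_end; humidity
    is derived from the temperature sinusoid via :func:`hr_from_ta`.
    """
    if sample_dt <= 0:
        raise ParameterError("sample_dt must be positive")
    n = int(math.floor((params.day_end - params.day_start) / sample_dt))
    t = params.day_start + sample_dt * np.arange(n + 1)
    if t[-1] < params.day_end:
        t = np.append(t, params.day_end)
    ppfd = ideal_light(t, params)
    ta = ideal_temperature(t, params)
    hr = hr_from_ta(ta)
    return ClimateSeries(
        t=t, ppfd=ppfd, ta=ta, hr=np.asarray(hr, dtype=float),
        ca=np.full_like(t, float(ca)),
        meta={
            "scenario": "ideal-day",
            "im": params.im, "ia": params.ia, "period": params.period,
            "tm": params.tm, "ta_amp": params.ta_amp, "lag": params.lag,
        },
    )
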