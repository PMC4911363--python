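"""Sensitivity experiments and synthetic fixtures.

Scans rerun a full diurnal simulation while varying exactly one parameter
(stomatal speed alpha_g, initial lag r0, target slope g1, mesophyll
conductance gm) or the light/temperature fluctuation period, and tabulate
the daily integrals and water use efficiency per value.  Percent scans are
defined relative to the default calibration.  The fixture generator writes
the ideal sunny/cloudy forcing files and synthetic stomatal induction
curves so the whole analysis runs without any external data.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import stomata
from .errors import ParameterError
from .forcing import CLOUDY, SUNNY, ClimateSeries, IdealDayParams, make_ideal_day
from .params import ModelParams
from .simulator import SimConfig, daily_wue, run
from .stomata import GSW_PER_GSC

__all__ = [
    "ALPHA_G_VALUES",
    "R0_VALUES",
    "alpha_g_grid",
    "ScanSpec",
    "scan",
    "period_scan",
    "make_fixtures",
]

# explicit published scan sets for the kinetic parameters
ALPHA_G_VALUES = (0.00682, 0.00338, 0.00134, 0.00109)  # s-1
R0_VALUES = (0.0106, 0.0012, 0.0002)                   # mol H2O m-2 s-1

SCANNABLE = ("alpha_g", "r0", "g1", "gm")


def alpha_g_grid(n: int = 15, lo: float = 0.00109, hi: float = 0.0101) -> np.ndarray:
    """Log-spaced stomatal-speed grid spanning the published extremes."""
    return np.geomspace(lo, hi, n)


def _scenario_forcing(scenario, period: float | None = None,
                      sample_dt: float = 60.0) -> ClimateSeries:
    if isinstance(scenario, ClimateSeries):
        return scenario
    if isinstance(scenario, IdealDayParams):
        base = scenario
    elif scenario == "ideal-sunny":
        base = SUNNY
    elif scenario == "ideal-cloudy":
        base = CLOUDY
    else:
        raise ParameterError(f"unknown scenario {scenario!r}")
    if period is not None:
        base = dataclasses.replace(base, period=float(period))
    return make_ideal_day(base, sample_dt=sample_dt)


@dataclass
class ScanSpec:
    """One-parameter sensitivity scan specification.

    Give either absolute ``values`` or ``percents`` (changes relative to
    the default value of ``param``).  ``scenario`` is "ideal-sunny",
    "ideal-cloudy", an :class:`IdealDayParams`, or any
    :class:`ClimateSeries`.
    """

    param: str
    values: tuple[float, ...] | None = None
    percents: tuple[float, ...] | None = None
    scenario: object = "ideal-sunny"
    config: SimConfig = field(default_factory=SimConfig)
    period: float | None = None

    def __post_init__(self) -> None:
        if self.param not in SCANNABLE:
            raise ParameterError(
                f"param must be one of {SCANNABLE}, got {self.param!r}"
            )
        if (self.values is None) == (self.percents is None):
            raise ParameterError("give exactly one of values / percents")
        vals = self.values if self.values is not None else self.percents
        if not all(np.isfinite(vals)):
            raise ParameterError("scan values must be finite")

    def resolved_values(self) -> list[float]:
        if self.values is not None:
            return [float(v) for v in self.values]
        base = self._base_value()
        return [base * (1.0 + pct / 100.0) for pct in self.percents]

    def _base_value(self) -> float:
        mp = self.config.params
        for group in (mp.stomata, mp.fvcb, mp.hydraulics, mp.aero):
            if hasattr(group, self.param):
                return float(getattr(group, self.param))
        raise ParameterError(f"cannot resolve default for {self.param!r}")


def _scan_row(spec: ScanSpec, value: float, forcing: ClimateSeries,
              scenario_name: str) -> dict:
    row = {"param": spec.param, "value": value, "scenario": scenario_name,
           "wue_mmol_per_mol": np.nan, "int_A": np.nan, "int_E": np.nan,
           "status": "ok"}
    try:
        cfg = dataclasses.replace(
            spec.config, params=spec.config.params.replace(**{spec.param: value})
        )
        trace = run(cfg, forcing)
        summary = daily_wue(trace, cfg.wue_window)
        row.update(wue_mmol_per_mol=summary.wue, int_A=summary.int_a,
                   int_E=summary.int_e)
    except Exception as exc:  # annotate the row rather than abort the scan
        row["status"] = f"error: {type(exc).__name__}: {exc}"
    return row


def scan(spec: ScanSpec) -> pd.DataFrame:
    """Run one full simulation per parameter value; all else fixed.

    Returns a DataFrame with columns
    ``param,value,wue_mmol_per_mol,int_A,int_E,scenario,status``; a failed
    run annotates its row instead of aborting the scan.
    """
    forcing = _scenario_forcing(spec.scenario, spec.period)
    name = spec.scenario if isinstance(spec.scenario, str) else "custom"
    rows = [_scan_row(spec, v, forcing, name) for v in spec.resolved_values()]
    df = pd.DataFrame(rows)
    return df[["param", "value", "wue_mmol_per_mol", "int_A", "int_E",
               "scenario", "status"]]


def period_scan(periods, scenario="ideal-sunny",
                config: SimConfig | None = None) -> pd.DataFrame:
    """Daily WUE versus light/temperature fluctuation period.

    Regenerates the ideal-day forcing for each period (same mean light,
    amplitude, and day length) and simulates each; absolute periods in
    seconds.
    """
    config = config or SimConfig()
    periods = [float(p) for p in periods]
    if any(p <= 0 for p in periods):
        raise ParameterError("periods must be positive")
    rows = []
    for period in periods:
        row = {"param": "period", "value": period,
               "scenario": scenario if isinstance(scenario, str) else "custom",
               "wue_mmol_per_mol": np.nan, "int_A": np.nan, "int_E": np.nan,
               "status": "ok"}
        try:
            forcing = _scenario_forcing(scenario, period)
            trace = run(config, forcing)
            summary = daily_wue(trace, config.wue_window)
            row.update(wue_mmol_per_mol=summary.wue, int_A=summary.int_a,
                       int_E=summary.int_e)
        except Exception as exc:
            row["status"] = f"error: {type(exc).__name__}: {exc}"
        rows.append(row)
    df = pd.DataFrame(rows)
    return df[["param", "value", "wue_mmol_per_mol", "int_A", "int_E",
               "scenario", "status"]]


def make_fixtures(seed: int, outdir: str | Path,
                  params: ModelParams | None = None) -> dict[str, Path]:
    """Write the synthetic fixture bundle used by the test-suite and docs.

    Produces ideal sunny/cloudy climate CSVs, a noise-free and a
    2%-multiplicative-noise stomatal induction curve generated from the
    default kinetic parameters, and a deliberately malformed climate CSV as
    a negative fixture.  Deterministic for a given seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = params or ModelParams()
    rng = np.random.default_rng(seed)
    paths: dict[str, Path] = {}

    for name, preset in (("sunny", SUNNY), ("cloudy", CLOUDY)):
        path = outdir / f"ideal_{name}.csv"
        make_ideal_day(preset).to_csv(path)
        paths[f"ideal_{name}"] = path

    sp = params.stomata
    g_target = 0.3 / GSW_PER_GSC  # plateau gsw of 0.3 mol m-2 s-1
    t, gsw = stomata.simulate_induction(sp, g_target, duration=2400.0)
    clean = outdir / "induction_clean.csv"
    pd.DataFrame({"t": t, "gsw": gsw}).to_csv(clean, index=False)
    paths["induction_clean"] = clean

    noisy_gsw = gsw * (1.0 + 0.02 * rng.standard_normal(gsw.size))
    noisy = outdir / "induction_noisy.csv"
    pd.DataFrame({"t": t, "gsw": noisy_gsw}).to_csv(noisy, index=False)
    paths["induction_noisy"] = noisy

    bad = outdir / "malformed_climate.csv"
    bad.write_text("time,ppfd,ta\n06:00:00,100,295.15\n")  # hr column missing
    paths["malformed_climate"] = bad
    return paths
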