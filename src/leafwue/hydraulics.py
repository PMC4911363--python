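"""Mesophyll water and solute balance.

The mesophyll is a single well-mixed compartment.  Its water content Wm
(mol H2O m-2) changes as the difference between xylem influx Fi and
transpirational efflux Fo; its solute amount Nm (mol m-2) grows with the
influx through xylem sap loading.  Water potential is the sum of an osmotic
(van 't Hoff) and a turgor (exponential pressure--volume) component, and the
xylem-to-mesophyll hydraulic conductance combines a light-dependent term
with an endogenous oscillation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import StateError
from .params import HydraulicParams

__all__ = [
    "WaterState",
    "WaterPotentials",
    "kx_radiation",
    "kx_oscillation",
    "hydraulic_conductance",
    "osmotic_potential",
    "turgor_pressure",
    "mesophyll_potential",
    "water_influx",
    "state_derivatives",
]


@dataclass
class WaterState:
    """Mesophyll water content and solute amount."""

    wm: float  # mol H2O m-2, in (0, wm_max]
    nm: float  # mol solute m-2, >= 0

    def validate(self, p: HydraulicParams) -> "WaterState":
        if not (0.0 < self.wm <= p.wm_max):
            raise StateError(f"wm={self.wm} outside (0, {p.wm_max}]")
        if self.nm < 0:
            raise StateError(f"nm={self.nm} must be >= 0")
        return self


@dataclass(frozen=True)
class WaterPotentials:
    """Osmotic, turgor, and total mesophyll water potential (MPa)."""

    psi_s: float
    psi_p: float

    @property
    def psi_m(self) -> float:
        return self.psi_s + self.psi_p


def kx_radiation(ppfd: float, p: HydraulicParams) -> float:
    """Light-dependent hydraulic conductance component (g H2O m-2 s-1 MPa-1).

    Linear in PPFD up to ``ppfd_lim``, saturating at ``a + b`` above it.
    """
    frac = min(ppfd / p.ppfd_lim, 1.0) if p.ppfd_lim > 0 else 1.0
    return p.a + p.b * frac


def kx_oscillation(t: float, p: HydraulicParams) -> float:
    """Endogenous oscillation of hydraulic conductance (g H2O m-2 s-1 MPa-1).

    ``t`` is seconds since midnight; the phase argument uses ``t`` expressed
    in the configured oscillation time unit (minutes by default, hours as an
    alternative reading).
    """
    t_osc = t / 60.0 if p.osc_time_unit == "minutes" else t / 3600.0
    return p.tau_c * math.cos(-math.pi * t_osc / 60.0 + 2.5 * math.pi) * (
        p.psi_x - p.psi_m_r
    )


def hydraulic_conductance(t: float, ppfd: float, p: HydraulicParams) -> float:
    """Total xylem-to-mesophyll conductance (mol H2O m-2 s-1 MPa-1).

    Sum of the radiation and oscillation components converted from g to mol
    H2O; floored at zero (a negative total conductance is unphysical and can
    arise from the oscillation term at low light).
    """
    kx = p.cv_f1 * (kx_radiation(ppfd, p) + kx_oscillation(t, p))
    return max(kx, 0.0)


def osmotic_potential(nm: float, wm: float, tl: float, p: HydraulicParams) -> float:
    """Osmotic potential psi_s (MPa) of the mesophyll sap, van 't Hoff form."""
    if wm <= 0:
        raise StateError(f"wm must be positive, got {wm}")
    return -p.cv_f2 * p.gas_constant * tl * nm / wm


def turgor_pressure(wm: float, p: HydraulicParams) -> float:
    """Turgor pressure psi_p (MPa): exponential pressure--volume relation.

    Equals the full turgor ``alpha`` at full hydration (wm = wm_max) and
    decays with elasticity ``beta`` as the cell loses water.
    """
    if wm > p.wm_max * (1.0 + 1e-12):
        raise StateError(f"wm={wm} exceeds wm_max={p.wm_max}")
    if wm <= 0:
        raise StateError(f"wm must be positive, got {wm}")
    return p.alpha * math.exp(-p.beta * (1.0 - wm / p.wm_max))


def mesophyll_potential(nm: float, wm: float, tl: float,
                        p: HydraulicParams) -> WaterPotentials:
    """Total mesophyll water potential and its components."""
    return WaterPotentials(
        psi_s=osmotic_potential(nm, wm, tl, p),
        psi_p=turgor_pressure(wm, p),
    )


def water_influx(kx: float, psi_m: float, p: HydraulicParams) -> float:
    """Water influx Fi (mol H2O m-2 s-1) driven by the xylem-mesophyll
    water potential difference."""
    return kx * (p.psi_x - psi_m)


def state_derivatives(fi: float, fo: float, p: HydraulicParams) -> tuple[float, float]:
    """Time derivatives (dWm/dt, dNm/dt) of the water/solute state."""
    return fi - fo, p.c_i * p.n_xy * fi
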