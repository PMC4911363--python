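"""Leaf microclimate: vapour pressure deficit, saturation slope, total
conductance, leaf temperature, and transpiration.

Leaf temperature comes from a linearised single-leaf energy balance
(Penman--Monteith form): net radiation is partitioned into sensible heat,
exchanged through the boundary layer at conductance g_aH = g_bw / 1.15, and
latent heat, exchanged through stomata and boundary layer in series at the
total water vapour conductance g_tw.  All conductances are molar
(mol m-2 s-1) and rho_a * c_p is the molar heat capacity of air.
"""
from __future__ import annotations

import math

from .errors import DomainError
from .params import AeroParams

__all__ = [
    "vpd",
    "svp_slope",
    "total_conductance",
    "net_radiation",
    "leaf_temperature",
    "transpiration",
]

T_ZERO_C = 273.16


def _sat_pressure(ta: float, p: AeroParams) -> float:
    """Saturation vapour pressure (kPa) at air temperature ``ta`` (K), Magnus form."""
    tc = ta - T_ZERO_C
    denom = p.a3 + tc
    if denom <= 0:
        raise DomainError(f"temperature {ta} K below the Magnus formula domain")
    return p.a1 * math.exp(p.a2 * tc / denom)


def vpd(ta: float, hr: float, p: AeroParams) -> float:
    """Vapour pressure deficit delta_e (kPa) of air at ``ta`` (K) and ``hr`` (%)."""
    if not (0.0 <= hr <= 100.0):
        raise DomainError(f"hr must be in [0, 100], got {hr}")
    return (1.0 - hr / 100.0) * _sat_pressure(ta, p)


def svp_slope(ta: float, de: float, p: AeroParams) -> float:
    """Slope s (kPa K-1) of the saturation vapour pressure curve.

    The default ``literal`` mode scales the Magnus derivative with the
    current deficit ``de`` (hence with 1 - hr/100); the ``saturation`` mode
    substitutes the saturation pressure itself, the thermodynamically
    standard slope independent of humidity.
    """
    tc = ta - T_ZERO_C
    denom = (p.a3 + tc) ** 2
    if p.slope_mode == "saturation":
        de = _sat_pressure(ta, p)
    return p.a2 * p.a3 * de / denom


def total_conductance(gsw: float, p: AeroParams) -> float:
    """Series combination of stomatal and boundary-layer conductance to
    water vapour (mol H2O m-2 s-1)."""
    if gsw < 0:
        raise DomainError(f"gsw must be >= 0, got {gsw}")
    denom = gsw + p.g_bw
    if denom == 0:
        return 0.0
    return p.g_bw * gsw / denom


def net_radiation(ppfd: float, p: AeroParams) -> float:
    """Net radiation Rn (J m-2 s-1) from PPFD via the linear conversion
    ``k_rad`` (default 0.4376 J umol-1: PAR energy content doubled to
    approximate total absorbed shortwave)."""
    return p.k_rad * ppfd


def leaf_temperature(ta: float, de: float, s: float, gtw: float, rn: float,
                     p: AeroParams) -> float:
    """Leaf temperature Tl (K) from the linearised energy balance.

    Closed form of Rn - Gi = H + lambda*E with H = rho_a*c_p*(Tl-Ta)*g_aH
    and the latent term linearised about Ta via slope ``s``.
    """
    if gtw <= 0:
        raise DomainError(f"gtw must be positive, got {gtw}")
    r_tw = 1.0 / gtw
    r_ah = 1.0 / p.g_ah
    rho_cp = p.rho_a * p.c_p
    denom = rho_cp * (p.gamma * r_tw + s * r_ah)
    if denom == 0:
        raise DomainError("degenerate energy balance: zero denominator")
    num = r_ah * r_tw * p.gamma * (rn - p.g_i) - r_ah * rho_cp * de
    return ta + num / denom


def transpiration(tl: float, ta: float, de: float, s: float, gtw: float,
                  p: AeroParams) -> float:
    """Transpiration rate E (mol H2O m-2 s-1) at leaf temperature ``tl``.

    Uses the linearised leaf-to-air vapour pressure difference
    de + s * (Tl - Ta).
    """
    if gtw < 0:
        raise DomainError(f"gtw must be >= 0, got {gtw}")
    return gtw * p.rho_a * p.c_p * (de + s * (tl - ta)) / (p.lam * p.gamma)
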