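"""FvCB photosynthesis with mesophyll conductance.

Net assimilation A is the minimum of a Rubisco-limited branch

    Ac = Vcmax * (Cc - Gamma*) / (Cc + Km)

and an RuBP-regeneration-limited branch

    Aj = J * (Cc - Gamma*) / (4 Cc + 8 Gamma*),

with the chloroplastic CO2 mole fraction Cc drawn down below ambient Ca by
the stomatal and mesophyll conductances in series:

    Cc = Ca - A * (G + gm) / (G * gm).

Two coupling modes are provided.  The *steady-state* mode closes the loop
with the stomatal target G = g0 + gscb * A, which turns each branch into a
cubic polynomial in A solved analytically; it yields the target pair
(A, G) the stomata relax toward.  The *instantaneous* mode takes the
current stomatal conductance as given, which reduces each branch to a
quadratic in A; it yields the assimilation actually realised while the
stomata are still moving.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ParameterError, SolverError
from .params import FvCBParams, StomatalParams
from .stomata import GSW_PER_GSC, target_coefficient

__all__ = [
    "SteadyStateSolution",
    "electron_transport",
    "cc_from_a",
    "cubic_ac",
    "cubic_aj",
    "solve_admissible_root",
    "steady_state",
    "instantaneous_a",
]

_REAL_TOL = 1e-8   # relative imaginary part below which a root is real
_NEG_TOL = 1e-9    # tolerance for clamping tiny negative A to zero


def electron_transport(iinc: float, p: FvCBParams) -> float:
    """Electron transport rate J (umol e- m-2 s-1) at incident PPFD ``iinc``.

    Smaller root of the non-rectangular hyperbola
    theta*J^2 - (kappa2_ll*Iinc + Jmax)*J + kappa2_ll*Iinc*Jmax = 0.
    """
    if not (0.0 < p.theta < 1.0):
        raise ParameterError(f"theta must be in (0, 1), got {p.theta}")
    if iinc < 0:
        raise ParameterError(f"iinc must be >= 0, got {iinc}")
    ki = p.kappa2_ll * iinc
    b = ki + p.jmax
    disc = b * b - 4.0 * p.theta * ki * p.jmax
    return (b - math.sqrt(max(disc, 0.0))) / (2.0 * p.theta)


def cc_from_a(a: float, g: float, p: FvCBParams) -> float:
    """Chloroplastic CO2 mole fraction (umol mol-1) implied by assimilation
    ``a`` at stomatal CO2 conductance ``g`` and mesophyll conductance gm."""
    if g <= 0 or p.gm <= 0:
        raise ParameterError("conductances must be positive")
    return p.ca - a * (g + p.gm) / (g * p.gm)


def cubic_ac(gscb: float, g0: float, p: FvCBParams) -> tuple[float, float, float, float]:
    """Coefficients (c3, c2, c1, c0) of the Rubisco-branch cubic in A."""
    g0m = g0 + p.gm
    p1 = p.ca - p.gamma_star
    p2 = p.ca + p.km
    c3 = gscb
    c2 = g0m - gscb * p.vcmax - gscb * p.gm * p2
    c1 = p.gm * p1 * p.vcmax * gscb - g0m * p.vcmax - g0 * p.gm * p2
    c0 = g0 * p.gm * p1 * p.vcmax
    return c3, c2, c1, c0


def cubic_aj(gscb: float, g0: float, j: float,
             p: FvCBParams) -> tuple[float, float, float, float]:
    """Coefficients (b3, b2, b1, b0) of the RuBP-regeneration-branch cubic in A."""
    if j < 0:
        raise ParameterError(f"j must be >= 0, got {j}")
    g0m = g0 + p.gm
    k1 = p.ca - p.gamma_star
    k2 = p.ca + 2.0 * p.gamma_star
    b3 = 4.0 * gscb
    b2 = 4.0 * g0m - j * gscb - 4.0 * k2 * p.gm * gscb
    b1 = k1 * p.gm * j * gscb - 4.0 * k2 * p.gm * g0 - j * g0m
    b0 = k1 * p.gm * j * g0
    return b3, b2, b1, b0


def _cubic_real_roots(a: float, b: float, c: float, d: float) -> list[float]:
    """Real roots of a*x^3 + b*x^2 + c*x + d via the depressed-cubic
    (Cardano/trigonometric) formulas, Newton-polished on the original
    polynomial to recover accuracy lost to cancellation."""
    p, q, r = b / a, c / a, d / a
    aa = q - p * p / 3.0
    bb = 2.0 * p ** 3 / 27.0 - p * q / 3.0 + r
    shift = p / 3.0
    disc = bb * bb / 4.0 + aa ** 3 / 27.0
    roots: list[float]
    if disc > 0.0:  # one real root
        sq = math.sqrt(disc)
        u = math.copysign(abs(-bb / 2.0 + sq) ** (1.0 / 3.0), -bb / 2.0 + sq)
        v = math.copysign(abs(-bb / 2.0 - sq) ** (1.0 / 3.0), -bb / 2.0 - sq)
        roots = [u + v - shift]
    elif aa == 0.0 and bb == 0.0:  # triple root
        roots = [-shift]
    else:  # three real roots (or a double), trigonometric form
        m = 2.0 * math.sqrt(max(-aa / 3.0, 0.0))
        arg = 3.0 * bb / (aa * m) if m > 0.0 else 0.0
        theta = math.acos(min(max(arg, -1.0), 1.0)) / 3.0
        roots = [
            m * math.cos(theta) - shift,
            m * math.cos(theta - 2.0 * math.pi / 3.0) - shift,
            m * math.cos(theta - 4.0 * math.pi / 3.0) - shift,
        ]
    polished = []
    for x in roots:
        for _ in range(2):  # Newton polish
            f = ((a * x + b) * x + c) * x + d
            fp = (3.0 * a * x + 2.0 * b) * x + c
            if fp == 0.0:
                break
            x -= f / fp
        polished.append(x)
    return polished


def _real_roots(coeffs: tuple[float, ...]) -> list[float]:
    """Real roots of a polynomial given leading-first coefficients.

    Degenerate leading coefficients reduce the degree; quadratics and
    linears are solved in closed form, cubics analytically with Newton
    polishing (cross-checked against the companion-matrix route in the
    test-suite).
    """
    c = list(coeffs)
    scale = max(abs(v) for v in c) or 1.0
    while len(c) > 1 and abs(c[0]) <= 1e-14 * scale:
        c.pop(0)
    if len(c) <= 1:
        return []
    if len(c) == 2:
        return [-c[1] / c[0]]
    if len(c) == 3:
        a, b, d = c
        disc = b * b - 4.0 * a * d
        if disc < 0:
            return []
        sq = math.sqrt(disc)
        return [(-b - sq) / (2.0 * a), (-b + sq) / (2.0 * a)]
    return _cubic_real_roots(*c)


def solve_admissible_root(coeffs: tuple[float, ...], gscb: float, g0: float,
                          p: FvCBParams) -> float:
    """Select the physically admissible assimilation rate among real roots.

    Admissibility: A >= 0, the implied Cc lies in (0, Ca], and the implied
    target conductance G = g0 + gscb*A is at least g0.  When several roots
    qualify the smallest is returned.  Raises :class:`SolverError` (with all
    roots attached) when none qualifies.
    """
    roots = _real_roots(coeffs)
    admissible = []
    for r in roots:
        a = 0.0 if -_NEG_TOL <= r < 0.0 else r
        if a < 0.0:
            continue
        g = g0 + gscb * a
        if g < g0 - 1e-15 or g <= 0:
            continue
        cc = cc_from_a(a, g, p)
        if not (0.0 < cc <= p.ca * (1.0 + 1e-12)):
            continue
        admissible.append(a)
    if not admissible:
        raise SolverError(
            f"no admissible assimilation root (gscb={gscb}, g0={g0})", roots=roots
        )
    return min(admissible)


@dataclass(frozen=True)
class SteadyStateSolution:
    """Joint steady state of assimilation and the stomatal target."""

    a: float            # net assimilation, umol CO2 m-2 s-1
    ac: float           # Rubisco-limited branch value
    aj: float           # RuBP-regeneration-limited branch value
    g: float            # target stomatal conductance to CO2, mol m-2 s-1
    cc: float           # chloroplastic CO2 mole fraction, umol mol-1
    limitation: str     # "rubisco" | "rubp"


def steady_state(de: float, psi_m: float, iinc: float, p: FvCBParams,
                 sp: StomatalParams) -> SteadyStateSolution:
    """Solve the coupled assimilation--stomatal-target steady state.

    Both branch cubics are solved with the same target slope gscb; the net
    rate is the branch minimum and the target conductance follows from it.
    """
    gscb = target_coefficient(de, psi_m, p.ca, sp)
    j = electron_transport(iinc, p)
    ac = solve_admissible_root(cubic_ac(gscb, sp.g0, p), gscb, sp.g0, p)
    if j == 0.0:
        aj = 0.0
    else:
        aj = solve_admissible_root(cubic_aj(gscb, sp.g0, j, p), gscb, sp.g0, p)
    if ac <= aj:
        a, limitation = ac, "rubisco"
    else:
        a, limitation = aj, "rubp"
    if p.subtract_rd:
        a = a - p.rd
    g = sp.g0 + gscb * max(a, 0.0)
    cc = cc_from_a(max(a, 0.0), g, p)
    return SteadyStateSolution(a=a, ac=ac, aj=aj, g=g, cc=cc, limitation=limitation)


def _branch_quadratic(rt: float, vmax_like: float, km_like: float,
                      p: FvCBParams) -> float:
    """Smaller root of rt*A^2 - (Ca + km_like + vmax_like*rt)*A
    + vmax_like*(Ca - Gamma*) = 0 (the drawdown-resistance quadratic)."""
    if vmax_like == 0.0:
        return 0.0
    b = p.ca + km_like + vmax_like * rt
    c = vmax_like * (p.ca - p.gamma_star)
    disc = b * b - 4.0 * rt * c
    if disc < 0:
        raise SolverError("no real root of the drawdown quadratic", roots=[])
    return (b - math.sqrt(disc)) / (2.0 * rt)


def instantaneous_a(gsc_now: float, iinc: float,
                    p: FvCBParams) -> tuple[float, float]:
    """Assimilation realised at the *current* stomatal CO2 conductance.

    With the total drawdown resistance rt = 1/gsc + 1/gm, each branch
    reduces to a quadratic in A; the smaller root is physical.  Returns
    (A, Cc).
    """
    if gsc_now <= 0:
        raise ParameterError(f"gsc_now must be positive, got {gsc_now}")
    rt = 1.0 / gsc_now + 1.0 / p.gm
    j = electron_transport(iinc, p)
    ac = _branch_quadratic(rt, p.vcmax, p.km, p)
    # RuBP branch: A = J(Cc - G*)/(4Cc + 8G*)  ->  scale by 4
    aj = _branch_quadratic(rt, j / 4.0, 2.0 * p.gamma_star, p)
    a = min(ac, aj)
    if p.subtract_rd:
        a = a - p.rd
    cc = p.ca - max(a, 0.0) * rt
    return a, cc
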