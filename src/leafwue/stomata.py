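"""Dynamic stomatal conductance.

Stomatal conductance to water vapour g_sw relaxes toward 1.6 times a
steady-state target conductance to CO2, G, with first-order-in-log kinetics

    dg_sw/dt = alpha_g * ln((1.6 G - r0) / (g_sw - r0)) * (g_sw - r0),

where alpha_g (s-1) sets the speed and r0 (mol m-2 s-1) the initial lag: a
conductance starting near r0 moves away from it slowly, reproducing the
delayed onset seen in light-induction experiments.  The target follows the
unified (Medlyn-type) optimal stomatal model gated by mesophyll water
potential:

    G = g0 + (1 + g1 / sqrt(de)) * (A / Ca) * f(psi_m).

Because G is linear in the assimilation rate A, the photosynthesis solver
receives only the slope gscb = (1 + g1/sqrt(de)) * f(psi_m) / Ca.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import FittingError, ParameterError
from .params import StomatalParams

__all__ = [
    "GSW_PER_GSC",
    "CLAMP_EPS",
    "f_psi",
    "target_coefficient",
    "gsw_derivative",
    "simulate_induction",
    "induction_trajectory",
    "InductionFit",
    "fit_induction",
]

GSW_PER_GSC = 1.6  # ratio of H2O to CO2 diffusivity in air
CLAMP_EPS = 1e-6   # floor above r0 applied to the log argument

_EXP_MAX = 700.0   # overflow guard for exp()


def _safe_exp(x: float) -> float:
    return math.exp(min(x, _EXP_MAX))


def f_psi(psi_m: float, p: StomatalParams) -> float:
    """Water-potential gating factor in (0, 1 + exp(s_f * psi_r)).

    Equals 1 at psi_m = 0 and falls sigmoidally to 0 as the mesophyll
    dries below the reference potential ``psi_r``.
    """
    num = 1.0 + _safe_exp(p.s_f * p.psi_r)
    den = 1.0 + _safe_exp(p.s_f * (p.psi_r - psi_m))
    return num / den


def target_coefficient(de: float, psi_m: float, ca: float,
                       p: StomatalParams) -> float:
    """Slope gscb of the steady-state target G = g0 + gscb * A.

    ``de`` is floored at ``de_min`` to avoid the 1/sqrt(de) singularity at
    vapour saturation.  Units: mol CO2 m-2 s-1 per umol CO2 m-2 s-1.
    """
    if ca <= 0:
        raise ParameterError(f"ca must be positive, got {ca}")
    de = max(de, p.de_min)
    return (1.0 + p.g1 / math.sqrt(de)) * f_psi(psi_m, p) / ca


def gsw_derivative(gsw: float, g_target: float, p: StomatalParams) -> float:
    """dg_sw/dt (mol H2O m-2 s-1 per s) toward the target 1.6 * G.

    Both the current conductance and the target are floored at
    r0 + CLAMP_EPS before entering the logarithm; the floor realises the
    initial-lag behaviour that r0 encodes.
    """
    floor = p.r0 + CLAMP_EPS
    g = max(gsw, floor)
    gt = max(GSW_PER_GSC * g_target, floor)
    return p.alpha_g * math.log((gt - p.r0) / (g - p.r0)) * (g - p.r0)


def induction_trajectory(t, alpha_g: float, r0: float, g_inf: float,
                         g_init: float):
    """Closed-form solution of the kinetic law at a constant target.

    With u = g_sw - r0 and U = g_inf - r0 the law integrates to a Gompertz
    curve u(t) = U * exp(ln(u0/U) * exp(-alpha_g t)).  ``g_inf`` is the
    asymptote 1.6*G and ``g_init`` the conductance at t = 0 (floored just
    above r0 if it starts below).
    """
    t = np.asarray(t, dtype=float)
    u0 = max(g_init - r0, CLAMP_EPS)
    U = max(g_inf - r0, CLAMP_EPS)
    z0 = math.log(U / u0)
    return r0 + U * np.exp(-z0 * np.exp(-alpha_g * t))


def simulate_induction(p: StomatalParams, g_constant: float, duration: float,
                       dt: float = 0.05, gsw0: float = 1e-4,
                       sample_every: float = 5.0):
    """Forward-integrate a light-induction experiment at a fixed target.

    Starts from a near-zero conductance ``gsw0`` (clamped just above r0)
    and integrates with explicit Euler at step ``dt``, emitting samples
    every ``sample_every`` seconds, mirroring the 5-s logging of a gas
    exchange analyser.  Returns (t, gsw) arrays.
    """
    if dt <= 0:
        raise ParameterError("dt must be positive")
    if sample_every < dt:
        raise ParameterError("sample_every must be >= dt")
    n = int(round(duration / dt))
    stride = max(int(round(sample_every / dt)), 1)
    gsw = max(gsw0, p.r0 + CLAMP_EPS)
    ts, gs = [0.0], [gsw]
    for k in range(1, n + 1):
        gsw += dt * gsw_derivative(gsw, g_constant, p)
        if k % stride == 0:
            ts.append(k * dt)
            gs.append(gsw)
    return np.asarray(ts), np.asarray(gs)


@dataclass(frozen=True)
class InductionFit:
    """Result of fitting the kinetic law to an induction curve."""

    alpha_g: float
    r0: float
    g_inf: float
    residual_norm: float
    converged: bool


def fit_induction(t, gsw, p0: tuple[float, float] | None = None) -> InductionFit:
    """Estimate (alpha_g, r0) from a measured induction curve.

    Fits the closed-form trajectory by nonlinear least squares with the
    asymptote ``g_inf`` as a third free parameter (initialised from the
    plateau) and the initial conductance taken from the first sample.
    Raises :class:`FittingError` when the curve carries no rise (flat
    series) or the optimiser fails.
    """
    t = np.asarray(t, dtype=float)
    gsw = np.asarray(gsw, dtype=float)
    if t.size < 20:
        raise FittingError(f"need >= 20 samples spanning the rise, got {t.size}")
    rise = float(np.max(gsw) - np.min(gsw))
    scale = float(np.max(np.abs(gsw)))
    if scale == 0 or rise < 1e-3 * scale:
        raise FittingError(
            "series is (near-)constant: kinetic parameters unidentifiable",
            diagnostics={"rise": rise, "scale": scale},
        )
    g_init = float(gsw[0])
    g_inf0 = float(np.mean(gsw[-max(3, t.size // 20):]))
    a0, r00 = p0 if p0 is not None else (5e-3, max(g_init, 1e-4))

    def residuals(theta):
        alpha_g, r0, g_inf = theta
        model = induction_trajectory(t - t[0], alpha_g, r0, g_inf, g_init)
        return model - gsw

    try:
        res = least_squares(
            residuals,
            x0=[a0, r00, g_inf0],
            bounds=([1e-6, 0.0, 1e-6], [1.0, 1.0, 10.0]),
            xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=5000,
        )
    except Exception as exc:
        raise FittingError(f"induction fit failed: {exc}") from exc
    if not res.success:
        raise FittingError(
            f"induction fit did not converge: {res.message}",
            diagnostics={"status": res.status, "cost": float(res.cost)},
        )
    alpha_g, r0, g_inf = (float(v) for v in res.x)
    return InductionFit(
        alpha_g=alpha_g, r0=r0, g_inf=g_inf,
        residual_norm=float(np.linalg.norm(res.fun)),
        converged=bool(res.success),
    )
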