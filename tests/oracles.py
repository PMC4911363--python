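"""Independent numerical oracles used to cross-check the analytical solvers.

These deliberately avoid the polynomial route of the implementation: the
steady state is found by bracketed root-finding on the implicit
assimilation equation, and leaf temperature by bisection on the raw energy
balance residual.
"""
from __future__ import annotations

from scipy.optimize import bisect, brentq

from leafwue.params import AeroParams, FvCBParams, StomatalParams
from leafwue.photosynthesis import electron_transport
from leafwue.stomata import target_coefficient


def steady_state_oracle(de: float, psi_m: float, iinc: float,
                        fp: FvCBParams, sp: StomatalParams) -> float:
    """Steady-state net assimilation by damped bracketing, no polynomials.

    For each branch, solves A = rate(Cc(A)) with
    Cc(A) = Ca - A (G + gm)/(G gm), G = g0 + gscb A, on a bracket bounded
    by the A at which Cc reaches the compensation point.  Returns the
    branch minimum.
    """
    gscb = target_coefficient(de, psi_m, fp.ca, sp)
    j = electron_transport(iinc, fp)

    def cc_of(a: float) -> float:
        g = sp.g0 + gscb * a
        return fp.ca - a * (g + fp.gm) / (g * fp.gm)

    def solve_branch(rate) -> float:
        if rate(fp.ca) <= 0.0:
            return 0.0

        def h(a: float) -> float:
            return a - rate(cc_of(a))

        # upper bracket: the A at which Cc reaches the compensation point
        # (rate vanishes there, so h > 0); Cc is monotone decreasing in A
        a_hi = 1e-6
        while cc_of(a_hi) > fp.gamma_star:
            a_hi *= 2.0
            if a_hi > 1e9:  # pragma: no cover - defensive
                raise RuntimeError("failed to bracket the steady state")
        a_bound = brentq(lambda a: cc_of(a) - fp.gamma_star, 0.0, a_hi,
                         xtol=1e-13, maxiter=200)
        return brentq(h, 0.0, a_bound, xtol=1e-13, rtol=8.9e-16, maxiter=200)

    ac = solve_branch(
        lambda cc: fp.vcmax * (cc - fp.gamma_star) / (cc + fp.km))
    if j == 0.0:
        aj = 0.0
    else:
        aj = solve_branch(
            lambda cc: j * (cc - fp.gamma_star) / (4.0 * cc + 8.0 * fp.gamma_star))
    return min(ac, aj)


def leaf_temperature_oracle(ta: float, de: float, s: float, gtw: float,
                            rn: float, ap: AeroParams) -> float:
    """Leaf temperature by bisection on the energy balance residual
    Rn - Gi = H + lambda*E with the linearised vapour pressure difference."""
    rho_cp = ap.rho_a * ap.c_p

    def residual(tl: float) -> float:
        h = rho_cp * (tl - ta) * ap.g_ah
        lam_e = gtw * rho_cp * (de + s * (tl - ta)) / ap.gamma
        return (rn - ap.g_i) - h - lam_e

    return bisect(residual, ta - 80.0, ta + 80.0, xtol=1e-12, maxiter=200)
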