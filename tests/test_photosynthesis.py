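import numpy as np
import pytest

import leafwue.photosynthesis as ph
from leafwue.errors import ParameterError, SolverError
from leafwue.params import FvCBParams, StomatalParams
from leafwue.stomata import target_coefficient

from oracles import steady_state_oracle


@pytest.fixture
def fp() -> FvCBParams:
    return FvCBParams()


@pytest.fixture
def sp() -> StomatalParams:
    return StomatalParams()


def random_physiology(rng):
    fp = FvCBParams(
        vcmax=rng.uniform(30, 150),
        jmax=rng.uniform(60, 250),
        theta=rng.uniform(0.5, 0.95),
        kappa2_ll=rng.uniform(0.2, 0.5),
        gm=rng.uniform(0.05, 1.8),
        ca=rng.uniform(300, 800),
    )
    sp = StomatalParams(
        g0=rng.uniform(1e-4, 0.05),
        g1=rng.uniform(0.5, 8.0),
        s_f=rng.uniform(2.0, 8.0),
    )
    de = rng.uniform(0.05, 3.5)
    psi = rng.uniform(-2.0, 0.5)
    iinc = rng.uniform(0.0, 2000.0)
    return de, psi, iinc, fp, sp


class TestElectronTransport:
    def test_dark(self, fp):
        assert ph.electron_transport(0.0, fp) == 0.0

    def test_saturation(self, fp):
        assert ph.electron_transport(1e7, fp) == pytest.approx(140.0, rel=1e-3)

    def test_mid_light(self, fp):
        assert ph.electron_transport(500.0, fp) == pytest.approx(110.27, abs=0.01)

    def test_invalid_theta(self):
        with pytest.raises(ParameterError):
            FvCBParams(theta=1.2)


class TestDrawdown:
    def test_no_assimilation_no_drawdown(self, fp):
        assert ph.cc_from_a(0.0, 0.1, fp) == fp.ca

    def test_arithmetic(self, fp):
        assert ph.cc_from_a(10.0, 0.1, fp) == pytest.approx(380 - 10 * 0.4 / 0.03)

    def test_infinite_conductances(self):
        fp = FvCBParams(gm=1e9)
        assert ph.cc_from_a(20.0, 1e9, fp) == pytest.approx(fp.ca, rel=1e-6)


class TestCubics:
    def test_degenerate_without_coupling(self, fp, sp):
        c3, *_ = ph.cubic_ac(0.0, sp.g0, fp)
        assert c3 == 0.0

    def test_constant_sign(self, fp, sp):
        *_, c0 = ph.cubic_ac(0.0118, sp.g0, fp)
        assert c0 > 0.0

    def test_branch_leading_ratio(self, fp, sp):
        gscb = 0.0118
        c = ph.cubic_ac(gscb, sp.g0, fp)
        b = ph.cubic_aj(gscb, sp.g0, 110.0, fp)
        assert b[0] == pytest.approx(4 * c[0])

    def test_j_zero_admits_zero_root(self, fp, sp):
        coeffs = ph.cubic_aj(0.0118, sp.g0, 0.0, fp)
        assert coeffs[-1] == 0.0
        assert ph.solve_admissible_root(coeffs, 0.0118, sp.g0, fp) == 0.0

    def test_coefficients_match_implicit_equation(self, fp, sp):
        """The admissible cubic root must satisfy the composed implicit
        equation A = rate(Cc(A)) of the branch it came from."""
        gscb = target_coefficient(1.0, 0.0, fp.ca, sp)
        a = ph.solve_admissible_root(ph.cubic_ac(gscb, sp.g0, fp), gscb, sp.g0, fp)
        g = sp.g0 + gscb * a
        cc = ph.cc_from_a(a, g, fp)
        assert a == pytest.approx(
            fp.vcmax * (cc - fp.gamma_star) / (cc + fp.km), rel=1e-9)

    def test_quadratic_fallback_matches_closed_form(self, fp, sp):
        """With gscb = 0 the target is fixed at g0 and the branch is the
        standard conductance-limited quadratic."""
        a = ph.solve_admissible_root(ph.cubic_ac(0.0, sp.g0, fp), 0.0, sp.g0, fp)
        rt = 1.0 / sp.g0 + 1.0 / fp.gm
        b = fp.ca + fp.km + fp.vcmax * rt
        c = fp.vcmax * (fp.ca - fp.gamma_star)
        expected = (b - np.sqrt(b * b - 4 * rt * c)) / (2 * rt)
        assert a == pytest.approx(expected, rel=1e-10)

    def test_no_admissible_root_raises(self, fp):
        with pytest.raises(SolverError) as err:
            ph.solve_admissible_root((0.0, 0.0, 1.0, 5.0), 0.0, 0.009, fp)
        assert err.value.roots  # roots carried for diagnosis


class TestSteadyState:
    def test_dark_state(self, fp, sp):
        ss = ph.steady_state(1.0, 0.0, 0.0, fp, sp)
        assert ss.a == 0.0
        assert ss.g == pytest.approx(sp.g0)
        assert ss.cc == pytest.approx(fp.ca)

    def test_min_rule(self, fp, sp):
        ss = ph.steady_state(1.0, 0.0, 500.0, fp, sp)
        assert ss.a == pytest.approx(min(ss.ac, ss.aj))
        assert ss.limitation in ("rubisco", "rubp")

    def test_residual_self_consistency(self, fp, sp):
        for iinc in (50.0, 200.0, 800.0, 1600.0):
            ss = ph.steady_state(1.2, -0.4, iinc, fp, sp)
            if ss.limitation == "rubisco":
                rate = fp.vcmax * (ss.cc - fp.gamma_star) / (ss.cc + fp.km)
            else:
                j = ph.electron_transport(iinc, fp)
                rate = j * (ss.cc - fp.gamma_star) / (4 * ss.cc + 8 * fp.gamma_star)
            assert ss.a == pytest.approx(rate, rel=1e-9)

    def test_oracle_equivalence_sample(self, fp, sp):
        rng = np.random.default_rng(7)
        for _ in range(25):
            de, psi, iinc, fpr, spr = random_physiology(rng)
            ss = ph.steady_state(de, psi, iinc, fpr, spr)
            ref = steady_state_oracle(de, psi, iinc, fpr, spr)
            assert ss.a == pytest.approx(ref, abs=1e-6)

    def test_monotone_in_mesophyll_conductance(self, sp):
        vals = []
        for gm in (0.05, 0.1, 0.3, 0.8, 1.8):
            fp = FvCBParams(gm=gm)
            vals.append(ph.steady_state(1.0, 0.0, 800.0, fp, sp).a)
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_monotone_in_light(self, fp, sp):
        vals = [ph.steady_state(1.0, 0.0, i, fp, sp).a
                for i in (0, 50, 150, 400, 1000, 2000)]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))


class TestInstantaneous:
    def test_fully_open_rubisco_limit(self):
        # jmax raised so the Rubisco branch limits at saturating light
        fp = FvCBParams(gm=1e9, jmax=2000.0)
        a, cc = ph.instantaneous_a(1e9, 1e7, fp)
        assert a == pytest.approx(102 * (380 - 43.02) / (380 + 711), abs=0.2)
        assert a == pytest.approx(31.50, abs=0.5)

    def test_dark(self, fp):
        a, cc = ph.instantaneous_a(0.1, 0.0, fp)
        assert a == 0.0
        assert cc == pytest.approx(fp.ca)

    def test_consistent_with_steady_state(self, fp, sp):
        ss = ph.steady_state(1.0, 0.0, 500.0, fp, sp)
        a, cc = ph.instantaneous_a(ss.g, 500.0, fp)
        assert a == pytest.approx(ss.a, rel=1e-9)
        assert cc == pytest.approx(ss.cc, rel=1e-9)

    def test_min_rule(self, fp):
        rt = 1 / 0.1 + 1 / fp.gm
        a, _ = ph.instantaneous_a(0.1, 300.0, fp)
        j = ph.electron_transport(300.0, fp)
        for vmax_like, km_like in ((fp.vcmax, fp.km), (j / 4, 2 * fp.gamma_star)):
            b = fp.ca + km_like + vmax_like * rt
            c = vmax_like * (fp.ca - fp.gamma_star)
            branch = (b - np.sqrt(b * b - 4 * rt * c)) / (2 * rt)
            assert a <= branch + 1e-12

    def test_requires_positive_conductance(self, fp):
        with pytest.raises(ParameterError):
            ph.instantaneous_a(0.0, 500.0, fp)
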