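"""Closed-form stresses and energies against independent oracles.

The analytic piecewise constants are checked against adaptive quadrature of
the recruitment integral, against a sympy re-derivation, and against
finite-difference derivatives of the strain energy.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

import tendonfit as tf
from tendonfit.constitutive import piecewise_coefficients

from conftest import random_triangle

triangles = st.builds(
    lambda a_off, width, frac: tf.TriangularRecruitment(
        1.0 + a_off, 1.0 + a_off + frac * width, 1.0 + a_off + width
    ),
    a_off=st.floats(0.005, 0.12),
    width=st.floats(0.01, 0.25),
    frac=st.floats(0.0, 1.0),
)

def deriv4(f, x, h):
    """Fourth-order central difference; the derivative oracle for energies."""
    return (-f(x + 2 * h) + 8 * f(x + h) - 8 * f(x - h) + f(x - 2 * h)) / (12 * h)


ST_T5C = np.array([8.36, 950.0, 1.04, 1.16])
TENDON_CDET = np.array([7.69, 1330.0, 0.192, 0.0115])
HGO_T5C = np.array([2.0, 6.41, 29.6])
GT_CANON = np.array([7.0, 800.0, 1.03, 1.08, 1.13])


# ---------------------------------------------------------------------------
# recruitment density
# ---------------------------------------------------------------------------

class TestRecruitmentPDF:
    def test_zero_outside_support(self):
        d = tf.TriangularRecruitment(1.01, 1.05, 1.10)
        assert tf.recruitment_pdf(d, 1.005) == 0.0
        assert tf.recruitment_pdf(d, 1.2) == 0.0

    def test_peak_value_at_mode(self, rng):
        for _ in range(10):
            d = random_triangle(rng)
            assert tf.recruitment_pdf(d, d.c) == pytest.approx(2.0 / (d.b - d.a), rel=1e-12)

    @pytest.mark.parametrize("a,c,b", [(1.04, 1.10, 1.16), (1.02, 1.02, 1.09), (1.02, 1.09, 1.09)])
    def test_integrates_to_one(self, a, c, b):
        d = tf.TriangularRecruitment(a, c, b)
        total, _ = quad(lambda x: tf.recruitment_pdf(d, x), a, b, points=[c])
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_invalid_construction_rejected(self):
        with pytest.raises(ValueError):
            tf.TriangularRecruitment(1.1, 1.15, 1.05)  # a >= b
        with pytest.raises(ValueError):
            tf.TriangularRecruitment(1.05, 1.2, 1.1)  # c outside [a, b]
        with pytest.raises(ValueError):
            tf.TriangularRecruitment(0.99, 1.0, 1.1)  # a <= 1


# ---------------------------------------------------------------------------
# single fibril
# ---------------------------------------------------------------------------

class TestFibrilStress:
    def test_slack_at_or_below_recruitment(self):
        assert tf.fibril_stress(800.0, 1.05, 1.05) == 0.0
        assert tf.fibril_stress(800.0, 1.02, 1.05) == 0.0

    def test_hookean_above_recruitment(self):
        assert tf.fibril_stress(800.0, 1.10, 1.05) == pytest.approx(800.0 * 0.05 / 1.05)
        # doubling the recruitment stretch gives stress E regardless of lam_r
        for lr in (1.0, 1.1, 1.3):
            assert tf.fibril_stress(800.0, 2 * lr, lr) == pytest.approx(800.0)

    def test_continuous_at_recruitment(self):
        eps = 1e-9
        assert tf.fibril_stress(800.0, 1.05 + eps, 1.05) < 1e-5


# ---------------------------------------------------------------------------
# population stress: analytic vs quadrature oracle
# ---------------------------------------------------------------------------

class TestPopulationStress:
    def test_analytic_matches_quadrature(self, rng):
        """Closed-form sigma_F equals adaptive quadrature to rel 1e-8."""
        for _ in range(120):
            d = random_triangle(rng, allow_degenerate=True)
            lam = float(rng.uniform(1.0, d.b + 0.15))
            num = tf.fibril_population_stress_numeric(d, 1.0, lam)
            ana = tf.fibril_population_stress(d, 1.0, lam * lam)
            assert ana == pytest.approx(num, rel=1e-8, abs=1e-11)

    def test_zero_below_onset(self, dist):
        assert tf.fibril_population_stress(dist, 800.0, 1.0) == 0.0
        assert tf.fibril_population_stress(dist, 800.0, dist.a ** 2) == pytest.approx(0.0, abs=1e-9)

    def test_linear_tail_slope_is_mean_inverse(self, rng):
        """For lam >= b the population stress is affine with slope E * E[1/lam_r]."""
        for _ in range(20):
            d = random_triangle(rng)
            E = 700.0
            lam = np.linspace(d.b, d.b + 0.1, 12)
            sf = tf.fibril_population_stress(d, E, lam * lam)
            slope, intercept = np.polyfit(lam, sf, 1)
            assert slope == pytest.approx(E * d.mean_inverse, rel=1e-8)
            assert intercept == pytest.approx(-E, rel=1e-8)
            # residual from the affine fit is zero: the tail is exactly linear
            assert np.max(np.abs(sf - (slope * lam + intercept))) < 1e-9 * E

    def test_continuity_at_regime_boundaries(self, rng):
        for _ in range(20):
            d = random_triangle(rng)
            for s in (d.a, d.c, d.b):
                for eps in (1e-6, 1e-8, 1e-10):
                    below = tf.fibril_population_stress(d, 1.0, (s - eps) ** 2)
                    above = tf.fibril_population_stress(d, 1.0, (s + eps) ** 2)
                    assert abs(above - below) < 50 * eps


@settings(max_examples=40, derandomize=True, deadline=None)
@given(d=triangles, e=st.floats(1.0, 2000.0))
def test_population_stress_monotone_and_slack_property(d, e):
    """sigma_F is zero before recruitment and nondecreasing in stretch."""
    lam = np.linspace(1.0, d.b + 0.1, 300)
    sf = tf.fibril_population_stress(d, e, lam * lam)
    assert np.all(sf[lam < d.a] == 0.0)
    assert np.all(np.diff(sf) >= -1e-9 * e)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(d=triangles, lam=st.floats(1.0, 1.5))
def test_energy_nonnegative_and_zero_when_slack_property(d, lam):
    w = tf.collagen_energy(d, 1.0, lam * lam)
    assert w >= -1e-12
    if lam <= d.a:
        assert w == pytest.approx(0.0, abs=1e-12)


class TestPiecewiseCoefficients:
    def test_slack_regime_is_zero(self, dist):
        co = piecewise_coefficients(dist, (dist.a - 0.01) ** 2)
        assert co.regime == "slack"
        assert (co.A, co.B, co.C, co.D, co.G) == (0, 0, 0, 0, 0)

    def test_regime_assignment(self, dist):
        assert piecewise_coefficients(dist, (dist.a + 1e-9) ** 2).regime == "partial"
        assert piecewise_coefficients(dist, (0.5 * (dist.c + dist.b)) ** 2).regime == "late"
        assert piecewise_coefficients(dist, (dist.b + 0.1) ** 2).regime == "full"

    def test_late_regime_constants_reproduce_quadrature(self, dist):
        """E(A + B lam + C lam^2 + D lam ln lam) equals the integral on a grid."""
        lams = np.linspace(dist.c + 1e-4, dist.b - 1e-4, 20)
        for lam in lams:
            co = piecewise_coefficients(dist, lam * lam)
            val = co.A + co.B * lam + co.C * lam ** 2 + co.D * lam * math.log(lam)
            num = tf.fibril_population_stress_numeric(dist, 1.0, float(lam))
            assert val == pytest.approx(num, rel=1e-8)


def _sympy_constants(a_val, c_val, b_val):
    """Independent symbolic integration of the recruitment integral.

    Returns (A, B, C, D) per regime by collecting the integral of
    f(lam_r) * (lam/lam_r - 1) in the basis {1, lam, lam^2, lam*log(lam)}.
    """
    import sympy as sp

    lam, lr = sp.symbols("lam lr", positive=True)
    a, c, b = sp.Rational(a_val), sp.Rational(c_val), sp.Rational(b_val)
    rising = 2 * (lr - a) / ((b - a) * (c - a)) if c != a else None
    falling = 2 * (b - lr) / ((b - a) * (b - c)) if c != b else None

    def collect(expr):
        expr = sp.expand(sp.simplify(expr))
        # basis {1, lam, lam**2, lam*log(lam)}
        D = sp.simplify(expr.coeff(sp.log(lam)) / lam)
        rest = sp.expand(expr - D * lam * sp.log(lam))
        poly = sp.Poly(rest, lam)
        coeffs = {1: poly.coeff_monomial(1), 2: poly.coeff_monomial(lam), 3: poly.coeff_monomial(lam ** 2)}
        return tuple(float(x) for x in (coeffs[1], coeffs[2], coeffs[3], D))

    out = {}
    integrand = lambda f: f * (lam / lr - 1)
    if rising is not None:
        out["partial"] = collect(sp.integrate(integrand(rising), (lr, a, lam)))
        upto_c = sp.integrate(integrand(rising), (lr, a, c))
    else:
        upto_c = sp.Integer(0)
    if falling is not None:
        out["late"] = collect(upto_c + sp.integrate(integrand(falling), (lr, c, lam)))
        full = upto_c + sp.integrate(integrand(falling), (lr, c, b))
    else:
        full = upto_c
    out["full"] = collect(full)
    return out


class TestSymbolicRederivation:
    @pytest.mark.parametrize(
        "a,c,b",
        [
            ("1.04", "1.10", "1.16"),  # general triangle
            ("1.03", "1.08", "1.13"),  # symmetric: c = (a+b)/2
            ("1.02", "1.02", "1.09"),  # degenerate c = a
            ("1.02", "1.09", "1.09"),  # degenerate c = b
        ],
    )
    def test_constants_match_sympy(self, a, c, b):
        """The implementation's piecewise constants equal a sympy re-derivation."""
        sym = _sympy_constants(a, c, b)
        d = tf.TriangularRecruitment(float(a), float(c), float(b))
        for regime, expected in sym.items():
            got = d._regime_table[regime]
            assert np.allclose(got, expected, rtol=1e-10, atol=1e-10), (regime, got, expected)

    def test_general_triangle_reduces_to_symmetric(self):
        """GT with c = (a+b)/2 equals the ST model pointwise to machine precision."""
        a, b = 1.03, 1.13
        st = tf.TriangularRecruitment.symmetric(a, b)
        gt = tf.TriangularRecruitment(a, 0.5 * (a + b), b)
        mat = tf.MaterialParams(7.0, 800.0)
        lam = np.linspace(1.0, 1.25, 101)
        np.testing.assert_array_equal(
            tf.engineering_stress(mat, st, lam), tf.engineering_stress(mat, gt, lam)
        )


# ---------------------------------------------------------------------------
# energies
# ---------------------------------------------------------------------------

class TestCollagenEnergy:
    def test_zero_for_slack_fibrils(self, dist):
        for i4 in (0.9, 1.0, dist.a ** 2):
            assert tf.collagen_energy(dist, 800.0, i4) == pytest.approx(0.0, abs=1e-12)

    def test_continuity_at_boundaries(self, rng):
        for _ in range(20):
            d = random_triangle(rng)
            for s in (d.a, d.c, d.b):
                eps = 1e-12
                below = tf.collagen_energy(d, 1.0, s * s * (1 - eps))
                above = tf.collagen_energy(d, 1.0, s * s * (1 + eps))
                assert above == pytest.approx(below, abs=1e-10)

    def test_stress_is_energy_derivative(self, dist):
        """2 * I4 * dW/dI4 recovers sigma_F on interior points (rel 1e-6)."""
        for lam in (1.07, 1.09, 1.12, 1.14, 1.20):
            i4 = lam * lam
            dw = deriv4(lambda x: tf.collagen_energy(dist, 1.0, x), i4, 1e-4 * i4)
            sf = tf.fibril_population_stress(dist, 1.0, i4)
            assert 2 * i4 * dw == pytest.approx(sf, rel=1e-6)


class TestTotalEnergy:
    def test_zero_in_reference_configuration(self, mat, dist):
        state = tf.UniaxialState.from_stretch(1.0)
        assert tf.total_energy(mat, dist, state) == 0.0

    def test_matrix_and_fibril_contributions_decouple(self, mat, dist):
        state = tf.UniaxialState.from_stretch(1.12)
        w = tf.total_energy(mat, dist, state)
        neo = 0.5 * mat.ncm_modulus * (state.i1 - 3.0)
        fib = mat.fibril_modulus * tf.collagen_energy(dist, 1.0, state.i4)
        assert w == pytest.approx(neo + fib, rel=1e-14)
        # below recruitment onset the energy is purely neo-Hookean
        state0 = tf.UniaxialState.from_stretch(1.02)
        assert tf.total_energy(mat, dist, state0) == pytest.approx(
            0.5 * mat.ncm_modulus * (state0.i1 - 3.0)
        )

    def test_uniaxial_state_invariants(self):
        s = tf.UniaxialState.from_stretch(1.3)
        assert s.i4 == pytest.approx(1.3 ** 2)
        assert s.i1 == pytest.approx(1.3 ** 2 + 2 / 1.3)
        assert tf.UniaxialState.from_stretch(1.0).i1 == pytest.approx(3.0)


# ---------------------------------------------------------------------------
# engineering stresses of the four models
# ---------------------------------------------------------------------------

MODEL_CASES = [
    ("st", ST_T5C),
    ("gt", GT_CANON),
    ("hgo", HGO_T5C),
    ("tendon", TENDON_CDET),
]


class TestEngineeringStress:
    @pytest.mark.parametrize("name,params", MODEL_CASES)
    def test_zero_at_reference(self, name, params):
        assert tf.get_model(name).stress(params, 1.0) == 0.0

    @pytest.mark.parametrize("name,params", MODEL_CASES)
    def test_energy_derivative_matches_stress(self, name, params):
        """Central-difference dW/dlam equals N(lam) away from regime boundaries."""
        spec = tf.get_model(name)
        for lam in (1.05, 1.09, 1.12, 1.18):
            dw = deriv4(lambda x: float(spec.energy(params, x)), lam, 1e-4)
            n = float(spec.stress(params, lam))
            assert dw == pytest.approx(n, rel=1e-6)

    @pytest.mark.parametrize("name,params", MODEL_CASES)
    def test_nondecreasing_on_tension(self, name, params):
        lam = np.linspace(1.0, 1.25, 400)
        n = tf.get_model(name).stress(params, lam)
        assert np.all(np.diff(n) > -1e-12)

    def test_cauchy_stress_construction_cross_check(self):
        """N equals lam^-1 (2 W1 (lam^2 - 1/lam) + 2 W4 lam^2) with p from sigma_rr = 0."""
        mat = tf.MaterialParams(8.36, 950.0)
        dist = tf.TriangularRecruitment.symmetric(1.04, 1.16)
        for lam in (1.06, 1.12, 1.19):
            i4 = lam * lam
            w1 = 0.5 * mat.ncm_modulus
            w4 = mat.fibril_modulus * deriv4(
                lambda x: tf.collagen_energy(dist, 1.0, x), i4, 1e-4 * i4
            )
            n_cauchy = (2 * w1 * (lam * lam - 1 / lam) + 2 * w4 * lam * lam) / lam
            assert n_cauchy == pytest.approx(
                float(tf.engineering_stress(mat, dist, lam)), rel=1e-6
            )


class TestHGO:
    def test_direct_evaluation(self):
        c, k1, k2, lam = 0.0, 6.41, 29.6, 1.05
        e4 = lam ** 2 - 1
        expected = 2 * k1 * lam * e4 * math.exp(k2 * e4 ** 2)
        p = tf.HGOParams(c, k1, k2)
        assert tf.engineering_stress_hgo(p, lam) == pytest.approx(expected, rel=1e-12)

    def test_k1_zero_reduces_to_neo_hookean(self):
        p = tf.HGOParams(5.0, 0.0, 10.0)
        lam = np.linspace(1.0, 1.3, 20)
        np.testing.assert_allclose(
            tf.engineering_stress_hgo(p, lam), 5.0 * (lam - lam ** -2), rtol=1e-14
        )

    def test_overflow_guarded(self):
        p = tf.HGOParams(1.0, 1.0, 1e6)
        out = tf.engineering_stress_hgo(p, 2.0)
        assert np.isinf(out) and out > 0


class TestTendonModel:
    def test_fibril_term_zero_below_shift(self):
        p = tf.ShearerTendonParams(*TENDON_CDET)
        lam = 1.0 + p.gamma / 2
        assert tf.engineering_stress_tendon(p, lam) == pytest.approx(
            p.ncm_modulus * (lam - lam ** -2), rel=1e-14
        )

    def test_continuity_at_branch_points(self):
        p = tf.ShearerTendonParams(*TENDON_CDET)
        for point in (1.0 + p.gamma, 1.0 / math.cos(p.theta_o) + p.gamma):
            lo = tf.engineering_stress_tendon(p, point - 1e-13)
            hi = tf.engineering_stress_tendon(p, point + 1e-13)
            assert abs(hi - lo) < 1e-9

    def test_third_branch_direct_evaluation(self):
        ncm, fib, theta, gamma = TENDON_CDET
        p = tf.ShearerTendonParams(ncm, fib, theta, gamma)
        lam = 1.05
        assert lam > 1.0 / math.cos(theta) + gamma
        sin2 = math.sin(theta) ** 2
        fib_term = fib * (2 * (1 - math.cos(theta) ** 3) / (3 * sin2) - 1 / (lam - gamma))
        expected = ncm * (lam - lam ** -2) + fib_term
        assert tf.engineering_stress_tendon(p, lam) == pytest.approx(expected, rel=1e-12)
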