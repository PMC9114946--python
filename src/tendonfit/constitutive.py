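"""Closed-form hyperelastic constitutive models for tendon.

Tendon is modelled as an incompressible, transversely isotropic composite of
a neo-Hookean non-collagenous matrix (NCM, shear modulus ``mu``) and a
population of initially crimped collagen fibrils (Young's modulus ``E``,
volume fraction ``phi``).  Each fibril is slack until the axial stretch
reaches its *recruitment stretch* ``lam_r`` and Hookean afterwards.  The
recruitment stretches follow a triangular probability density on
``[a, b]`` with mode ``c`` (the symmetric case has ``c = (a + b) / 2``),
which makes the population stress

    sigma_F(I4) = E * (A + B*sqrt(I4) + C*I4 + (D/2)*sqrt(I4)*log(I4))

piecewise analytic in the fourth invariant ``I4 = lam**2``, with constants
``A, B, C, D`` that change between four recruitment regimes (slack /
partially recruited below the mode / partially recruited above the mode /
fully recruited).  The associated strain-energy contribution

    W_coll(I4) = E * (A/2*log(I4) + (B - D)*sqrt(I4) + C/2*I4
                      + (D/2)*sqrt(I4)*log(I4) + G)

uses a per-regime constant ``G`` that makes the energy continuous and zero
at the onset of recruitment.  Two benchmark models are provided alongside:
the transversely isotropic Holzapfel--Gasser--Ogden (HGO) model and a
microstructural crimp-angle tendon model extended with a recruitment-shift
strain ``gamma``.

Only the products ``(1 - phi) * mu`` and ``phi * E`` are identifiable from
uniaxial data, so material parameters are carried as those two moduli.

All stresses are engineering (nominal) stresses in MPa; the canonical
abscissa is the axial stretch ``lam`` (engineering strain = ``lam - 1``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import cached_property

import numpy as np
from scipy.integrate import quad

__all__ = [
    "TriangularRecruitment",
    "MaterialParams",
    "HGOParams",
    "ShearerTendonParams",
    "UniaxialState",
    "PiecewiseCoefficients",
    "recruitment_pdf",
    "fibril_stress",
    "fibril_population_stress_numeric",
    "piecewise_coefficients",
    "fibril_population_stress",
    "collagen_energy",
    "total_energy",
    "engineering_stress",
    "engineering_stress_hgo",
    "engineering_stress_tendon",
    "uniaxial_energy_hgo",
    "uniaxial_energy_tendon",
]

# Regime labels, ordered by increasing I4.
SLACK, PARTIAL, LATE, FULL = "slack", "partial", "late", "full"

# Exponent beyond which exp() would overflow double precision.
_EXP_MAX = 700.0


@dataclass(frozen=True)
class TriangularRecruitment:
    """Triangular recruitment-stretch distribution on ``[a, b]`` with mode ``c``.

    ``a`` is the stretch at which the first fibril becomes taut, ``b`` the
    stretch at which the last does.  ``c = a`` and ``c = b`` are allowed as
    one-sided limits of the general triangle.
    """

    a: float
    c: float
    b: float

    def __post_init__(self) -> None:
        if not (1.0 < self.a < self.b):
            raise ValueError(f"require 1 < a < b, got a={self.a}, b={self.b}")
        if not (self.a <= self.c <= self.b):
            raise ValueError(f"mode c={self.c} outside [a, b]=[{self.a}, {self.b}]")

    @classmethod
    def symmetric(cls, a: float, b: float) -> "TriangularRecruitment":
        """The symmetric triangle (ST model): mode halfway between a and b."""
        return cls(a, 0.5 * (a + b), b)

    @cached_property
    def mean_inverse(self) -> float:
        """E[1 / lam_r]; the slope of the fully recruited stress is E * mean_inverse."""
        return self._regime_table[FULL][1]

    @cached_property
    def _regime_table(self) -> dict:
        """Per-regime stress constants (A, B, C, D) from analytic integration.

        The population stress is the convolution of Hooke's law with the
        triangular density; integrating the rising and falling branches of
        the density gives polynomial + log terms collected here.  Degenerate
        modes (c == a or c == b) drop the corresponding branch.
        """
        a, c, b = self.a, self.c, self.b
        table = {SLACK: (0.0, 0.0, 0.0, 0.0)}
        if c > a:
            k1 = 2.0 / ((b - a) * (c - a))
            table[PARTIAL] = (-0.5 * k1 * a * a, k1 * a * math.log(a), 0.5 * k1, -k1 * a)
            m0_c = (c - a) / (b - a)
            m1_c = k1 * ((c - a) - a * math.log(c / a))
        else:
            m0_c, m1_c = 0.0, 0.0
        if c < b:
            k2 = 2.0 / ((b - a) * (b - c))
            table[LATE] = (
                -m0_c + k2 * (b * c - 0.5 * c * c),
                m1_c + k2 * (c - b - b * math.log(c)),
                -0.5 * k2,
                k2 * b,
            )
            m1 = m1_c + k2 * (b * math.log(b / c) - (b - c))
        else:
            m1 = m1_c
        table[FULL] = (-1.0, m1, 0.0, 0.0)
        return table

    @cached_property
    def _energy_offsets(self) -> dict:
        """Continuity constants G per regime so W_coll is continuous and W_coll(a^2) = 0."""
        a, c, b = self.a, self.c, self.b
        offsets = {SLACK: 0.0}
        prev_regime, prev_bound = SLACK, a * a
        for regime, bound in ((PARTIAL, c * c), (LATE, b * b), (FULL, None)):
            if regime not in self._regime_table:
                continue
            w_left = _energy_raw(prev_bound, *self._regime_table[prev_regime]) + offsets[prev_regime]
            offsets[regime] = w_left - _energy_raw(prev_bound, *self._regime_table[regime])
            prev_regime, prev_bound = regime, bound
        return offsets

    def regime(self, i4: float) -> str:
        """Recruitment regime of a scalar I4 (half-open intervals, slack first)."""
        if i4 < self.a * self.a:
            return SLACK
        if i4 < self.c * self.c and PARTIAL in self._regime_table:
            return PARTIAL
        if i4 < self.b * self.b and LATE in self._regime_table:
            return LATE
        return FULL

    def _regime_masks(self, lam: np.ndarray):
        """Boolean masks selecting each non-slack regime on a stretch array."""
        out = []
        if PARTIAL in self._regime_table:
            out.append((PARTIAL, (lam >= self.a) & (lam < self.c)))
        if LATE in self._regime_table:
            out.append((LATE, (lam >= self.c) & (lam < self.b)))
        out.append((FULL, lam >= self.b))
        return out


@dataclass(frozen=True)
class MaterialParams:
    """Identifiable moduli of the recruitment models: (1 - phi)*mu and phi*E, in MPa."""

    ncm_modulus: float
    fibril_modulus: float

    def __post_init__(self) -> None:
        if self.ncm_modulus <= 0 or self.fibril_modulus <= 0:
            raise ValueError("moduli must be strictly positive")


@dataclass(frozen=True)
class HGOParams:
    """Transversely isotropic HGO parameters: c_hgo, k1 (MPa) and dimensionless k2."""

    c_hgo: float
    k1: float
    k2: float

    def __post_init__(self) -> None:
        if self.c_hgo < 0 or self.k1 < 0 or self.k2 <= 0:
            raise ValueError("HGO parameters must be positive (c_hgo, k1 may be 0 as limits)")


@dataclass(frozen=True)
class ShearerTendonParams:
    """Crimp-angle tendon model with recruitment shift.

    ``theta_o`` is the initial crimp angle (radians) of the outermost,
    most-crimped fibrils; ``gamma`` is the engineering strain at which the
    first fibril tautens, entering through I4 = (lam - gamma)**2.
    """

    ncm_modulus: float
    fibril_modulus: float
    theta_o: float
    gamma: float

    def __post_init__(self) -> None:
        if self.ncm_modulus <= 0 or self.fibril_modulus <= 0:
            raise ValueError("moduli must be strictly positive")
        if not (0.0 < self.theta_o < 0.5 * math.pi):
            raise ValueError("theta_o must lie in (0, pi/2)")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")


@dataclass(frozen=True)
class UniaxialState:
    """Kinematics of incompressible uniaxial extension along the fibril axis."""

    lam: float
    i1: float
    i4: float

    @classmethod
    def from_stretch(cls, lam: float) -> "UniaxialState":
        if lam <= 0:
            raise ValueError("stretch must be positive")
        return cls(lam=lam, i1=lam * lam + 2.0 / lam, i4=lam * lam)


@dataclass(frozen=True)
class PiecewiseCoefficients:
    """Regime-wise stress constants A-D and energy-continuity constant G."""

    regime: str
    A: float
    B: float
    C: float
    D: float
    G: float


def _energy_raw(i4: float, A: float, B: float, C: float, D: float) -> float:
    """Antiderivative of sigma_F / (2 E I4) with respect to I4, without its constant."""
    s = math.sqrt(i4)
    return 0.5 * A * math.log(i4) + (B - D) * s + 0.5 * C * i4 + 0.5 * D * s * math.log(i4)


def recruitment_pdf(dist: TriangularRecruitment, lam_r) -> np.ndarray:
    """Triangular recruitment-stretch density f(lam_r); zero outside [a, b]."""
    a, c, b = dist.a, dist.c, dist.b
    shape = np.shape(lam_r)
    x = np.atleast_1d(np.asarray(lam_r, dtype=float))
    out = np.zeros_like(x)
    if c > a:
        rising = (x >= a) & (x <= c)
        out[rising] = 2.0 * (x[rising] - a) / ((b - a) * (c - a))
    if c < b:
        falling = (x > c) & (x <= b) if c > a else (x >= a) & (x <= b)
        out[falling] = 2.0 * (b - x[falling]) / ((b - a) * (b - c))
    out = out.reshape(shape)
    if out.ndim == 0:
        return out[()]
    return out


def fibril_stress(E: float, lam, lam_r) -> np.ndarray:
    """Single-fibril stress: slack below its recruitment stretch, Hookean above.

    sigma_fib = E * (lam - lam_r) / lam_r for lam > lam_r, else 0.
    """
    lam = np.asarray(lam, dtype=float)
    lam_r = np.asarray(lam_r, dtype=float)
    out = np.where(lam > lam_r, E * (lam - lam_r) / lam_r, 0.0)
    if out.ndim == 0:
        return out[()]
    return out


def fibril_population_stress_numeric(
    dist: TriangularRecruitment,
    E: float,
    lam: float,
    rtol: float = 1e-12,
    atol: float = 1e-14,
) -> float:
    """Population stress by adaptive quadrature of f(lam_r) * sigma_fib over [0, lam].

    This is the independent oracle for :func:`fibril_population_stress`; the
    integrand is only supported on [a, min(lam, b)] and has a kink at the
    mode, which is passed to the integrator as a breakpoint.
    """
    if lam <= dist.a:
        return 0.0
    hi = min(lam, dist.b)
    pts = [p for p in (dist.c,) if dist.a < p < hi]

    def integrand(lr: float) -> float:
        return recruitment_pdf(dist, lr) * fibril_stress(E, lam, lr)

    value, err = quad(integrand, dist.a, hi, points=pts, limit=400, epsabs=atol, epsrel=rtol)
    if err > max(atol, abs(value) * 1e-8):
        raise RuntimeError(
            f"quadrature did not converge: estimate {value!r} with error bound {err!r}"
        )
    return value


def piecewise_coefficients(dist: TriangularRecruitment, i4: float) -> PiecewiseCoefficients:
    """Stress/energy constants (A, B, C, D, G) for the regime containing i4."""
    if i4 <= 0:
        raise ValueError("i4 must be positive")
    regime = dist.regime(i4)
    A, B, C, D = dist._regime_table[regime]
    return PiecewiseCoefficients(regime, A, B, C, D, dist._energy_offsets[regime])


def fibril_population_stress(dist: TriangularRecruitment, E: float, i4) -> np.ndarray:
    """Closed-form population (Cauchy) stress sigma_F as a function of I4.

    Piecewise analytic and continuous across the regime boundaries
    sqrt(I4) in {a, c, b}; linear in sqrt(I4) once all fibrils are taut.
    """
    i4 = np.asarray(i4, dtype=float)
    if np.any(i4 <= 0):
        raise ValueError("i4 must be positive")
    lam = np.sqrt(np.atleast_1d(i4))
    out = np.zeros_like(lam)
    for regime, mask in dist._regime_masks(lam):
        if not np.any(mask):
            continue
        A, B, C, D = dist._regime_table[regime]
        lm = lam[mask]
        out[mask] = A + B * lm + C * lm * lm + D * lm * np.log(lm)
    result = E * out.reshape(np.shape(i4))
    if result.ndim == 0:
        return result[()]
    return result


def collagen_energy(dist: TriangularRecruitment, E: float, i4) -> np.ndarray:
    """Fibril strain-energy density W_coll(I4), from sigma_F = 2 I4 dW/dI4.

    Continuous everywhere and zero for I4 <= a**2 (slack fibrils store no
    energy); the per-regime constants G enforce continuity.
    """
    i4 = np.asarray(i4, dtype=float)
    if np.any(i4 <= 0):
        raise ValueError("i4 must be positive")
    lam = np.sqrt(np.atleast_1d(i4))
    out = np.zeros_like(lam)
    for regime, mask in dist._regime_masks(lam):
        if not np.any(mask):
            continue
        A, B, C, D = dist._regime_table[regime]
        G = dist._energy_offsets[regime]
        x = lam[mask] ** 2
        s = lam[mask]
        out[mask] = (
            0.5 * A * np.log(x) + (B - D) * s + 0.5 * C * x + 0.5 * D * s * np.log(x) + G
        )
    result = E * out.reshape(np.shape(i4))
    if result.ndim == 0:
        return result[()]
    return result


def total_energy(mat: MaterialParams, dist: TriangularRecruitment, state: UniaxialState) -> float:
    """Total strain-energy density: neo-Hookean NCM plus recruited-fibril energy.

    W = (1 - phi) mu / 2 * (I1 - 3) + phi E * W_coll(I4) / E, expressed with
    the identifiable moduli; zero in the reference configuration.
    """
    ncm = 0.5 * mat.ncm_modulus * (state.i1 - 3.0)
    fib = mat.fibril_modulus * collagen_energy(dist, 1.0, state.i4)
    return ncm + fib


def engineering_stress(mat: MaterialParams, dist: TriangularRecruitment, lam) -> np.ndarray:
    """Uniaxial engineering stress N(lam) of the recruitment (ST/GT) model.

    N = (1 - phi) mu (lam - 1/lam^2) + phi E (A/lam + B + C lam + D log lam),
    obtained from the Cauchy stress with the incompressibility pressure
    eliminated by the traction-free lateral surface, divided by lam.
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch must be positive")
    sigma_f = fibril_population_stress(dist, 1.0, lam * lam)
    out = mat.ncm_modulus * (lam - lam ** -2) + mat.fibril_modulus * sigma_f / lam
    if out.ndim == 0:
        return out[()]
    return out


def engineering_stress_hgo(p: HGOParams, lam) -> np.ndarray:
    """Uniaxial engineering stress of the transversely isotropic HGO model.

    N = c_hgo (lam - 1/lam^2)
        + 2 k1 lam (lam^2 - 1) exp(k2 (lam^2 - 1)^2).

    The exponent is clipped at the overflow threshold; parameter vectors
    that would overflow return +/-inf, which samplers treat as a rejection.
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch must be positive")
    e4 = lam * lam - 1.0
    expo = p.k2 * e4 * e4
    fib = 2.0 * p.k1 * lam * e4 * np.exp(np.minimum(expo, _EXP_MAX))
    fib = np.where(expo > _EXP_MAX, np.copysign(np.inf, e4), fib)
    out = p.c_hgo * (lam - lam ** -2) + fib
    if out.ndim == 0:
        return out[()]
    return out


def uniaxial_energy_hgo(p: HGOParams, lam) -> np.ndarray:
    """HGO strain-energy density along the uniaxial path (I1, I4 in terms of lam)."""
    lam = np.asarray(lam, dtype=float)
    i1 = lam * lam + 2.0 / lam
    e4 = lam * lam - 1.0
    expo = np.minimum(p.k2 * e4 * e4, _EXP_MAX)
    out = 0.5 * p.c_hgo * (i1 - 3.0) + p.k1 / (2.0 * p.k2) * (np.exp(expo) - 1.0)
    if out.ndim == 0:
        return out[()]
    return out


def _tendon_fibril_branches(theta_o: float):
    """Branch functions and continuity constant of the crimp-angle fibril stress."""
    sin2 = math.sin(theta_o) ** 2
    cos = math.cos(theta_o)
    q = 2.0 * (1.0 - cos ** 3) / (3.0 * sin2)
    s_star = 1.0 / cos

    def n_mid(s):
        return (2.0 - 3.0 / s + s ** -3) / (3.0 * sin2)

    def n_top(s):
        return q - 1.0 / s

    def w_mid(s):
        return (4.0 * s - 6.0 * np.log(s) - s ** -2 - 3.0) / (6.0 * sin2)

    g3 = w_mid(s_star) - (q * s_star - math.log(s_star))

    def w_top(s):
        return q * s - np.log(s) + g3

    return s_star, n_mid, n_top, w_mid, w_top


def engineering_stress_tendon(p: ShearerTendonParams, lam) -> np.ndarray:
    """Uniaxial engineering stress of the shifted crimp-angle tendon model.

    The fibril term vanishes below lam = 1 + gamma, follows the sequential
    crimp-straightening branch up to lam = 1/cos(theta_o) + gamma, and is
    fully recruited above; both branch points are continuous.
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch must be positive")
    s = np.atleast_1d(lam - p.gamma)
    s_star, n_mid, n_top, _, _ = _tendon_fibril_branches(p.theta_o)
    fib = np.zeros_like(s)
    mid = (s >= 1.0) & (s <= s_star)
    top = s > s_star
    fib[mid] = n_mid(s[mid])
    fib[top] = n_top(s[top])
    out = p.ncm_modulus * (lam - lam ** -2) + p.fibril_modulus * fib.reshape(np.shape(lam))
    if out.ndim == 0:
        return out[()]
    return out


def uniaxial_energy_tendon(p: ShearerTendonParams, lam) -> np.ndarray:
    """Strain-energy density of the shifted tendon model along the uniaxial path."""
    lam = np.asarray(lam, dtype=float)
    s = np.atleast_1d(lam - p.gamma)
    s_star, _, _, w_mid, w_top = _tendon_fibril_branches(p.theta_o)
    fib = np.zeros_like(s)
    mid = (s >= 1.0) & (s <= s_star)
    top = s > s_star
    fib[mid] = w_mid(s[mid])
    fib[top] = w_top(s[top])
    i1 = lam * lam + 2.0 / lam
    out = 0.5 * p.ncm_modulus * (i1 - 3.0) + p.fibril_modulus * fib.reshape(np.shape(lam))
    if out.ndim == 0:
        return out[()]
    return out
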