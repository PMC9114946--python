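"""Registry of uniaxial stress models and their unconstrained parameterizations.

Each registered model exposes the engineering stress and strain-energy
density on the natural parameter scale plus a smooth bijection to an
unconstrained coordinate vector.  The bijections encode the physical
constraints (positive moduli; ordered recruitment stretches 1 < a < c < b;
crimp angle in (0, pi/2); non-negative shift strain) so that both the
Nelder--Mead fitter and the random-walk Metropolis sampler can work on all
of R^h.  The log-determinant of the Jacobian of the *inverse* map (needed
for the pullback posterior density) is available in closed form.

Registry names: ``st`` (symmetric triangular recruitment), ``gt`` (general
triangular), ``hgo`` (Holzapfel--Gasser--Ogden benchmark), ``tendon``
(crimp-angle model with recruitment shift).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.special import expit, logit

from . import constitutive as cst

__all__ = ["ModelSpec", "MODELS", "get_model"]


@dataclass(frozen=True)
class ModelSpec:
    """A uniaxial stress model plus its unconstrained coordinates.

    ``stress(params, lam)`` and ``energy(params, lam)`` take natural-scale
    parameter vectors (ordered as ``param_names``).  ``to_unconstrained`` /
    ``from_unconstrained`` are mutually inverse; ``log_jacobian(theta)`` is
    log|det D(from_unconstrained)(theta)|.
    """

    name: str
    param_names: tuple
    transformed_names: tuple
    stress: Callable
    energy: Callable
    to_unconstrained: Callable
    from_unconstrained: Callable
    log_jacobian: Callable
    validate: Callable

    @property
    def n_params(self) -> int:
        return len(self.param_names)


# ---------------------------------------------------------------------------
# Recruitment (ST / GT) models
# ---------------------------------------------------------------------------

def _st_objects(params):
    ncm, fib, a, b = params
    return cst.MaterialParams(ncm, fib), cst.TriangularRecruitment.symmetric(a, b)


def _gt_objects(params):
    ncm, fib, a, c, b = params
    return cst.MaterialParams(ncm, fib), cst.TriangularRecruitment(a, c, b)


def _st_stress(params, lam):
    mat, dist = _st_objects(params)
    return cst.engineering_stress(mat, dist, lam)


def _gt_stress(params, lam):
    mat, dist = _gt_objects(params)
    return cst.engineering_stress(mat, dist, lam)


def _recruitment_energy(objects):
    def energy(params, lam):
        mat, dist = objects(params)
        lam = np.asarray(lam, dtype=float)
        i1 = lam * lam + 2.0 / lam
        return 0.5 * mat.ncm_modulus * (i1 - 3.0) + mat.fibril_modulus * cst.collagen_energy(
            dist, 1.0, lam * lam
        )

    return energy


def _st_to_unconstrained(params):
    ncm, fib, a, b = params
    return np.array([math.log(ncm), math.log(fib), math.log(a - 1.0), math.log(b - a)])


def _st_from_unconstrained(theta):
    nu, eta, tau, rho = theta
    a = 1.0 + math.exp(tau)
    return np.array([math.exp(nu), math.exp(eta), a, a + math.exp(rho)])


def _gt_to_unconstrained(params):
    ncm, fib, a, c, b = params
    return np.array(
        [math.log(ncm), math.log(fib), math.log(a - 1.0), math.log(c - a), math.log(b - c)]
    )


def _gt_from_unconstrained(theta):
    nu, eta, tau, kappa, rho = theta
    a = 1.0 + math.exp(tau)
    c = a + math.exp(kappa)
    return np.array([math.exp(nu), math.exp(eta), a, c, c + math.exp(rho)])


def _sum_log_jacobian(theta):
    # Increment maps a = 1 + e^tau, c = a + e^kappa, ... are lower triangular
    # in these coordinates, so the determinant is the product of exponentials.
    return float(np.sum(theta))


def _st_validate(params, lam_max=None):
    ncm, fib, a, b = params
    ok = ncm > 0 and fib > 0 and 1.0 < a < b
    if lam_max is not None:
        ok = ok and a < lam_max
    return ok


def _gt_validate(params, lam_max=None):
    ncm, fib, a, c, b = params
    ok = ncm > 0 and fib > 0 and 1.0 < a < c < b
    if lam_max is not None:
        ok = ok and a < lam_max
    return ok


# ---------------------------------------------------------------------------
# HGO benchmark
# ---------------------------------------------------------------------------

def _hgo_stress(params, lam):
    return cst.engineering_stress_hgo(cst.HGOParams(*params), lam)


def _hgo_energy(params, lam):
    return cst.uniaxial_energy_hgo(cst.HGOParams(*params), lam)


def _hgo_to_unconstrained(params):
    return np.log(np.asarray(params, dtype=float))


def _hgo_from_unconstrained(theta):
    return np.exp(np.asarray(theta, dtype=float))


def _hgo_validate(params, lam_max=None):
    c_hgo, k1, k2 = params
    return c_hgo > 0 and k1 > 0 and k2 > 0


# ---------------------------------------------------------------------------
# Crimp-angle tendon model
# ---------------------------------------------------------------------------

def _tendon_stress(params, lam):
    return cst.engineering_stress_tendon(cst.ShearerTendonParams(*params), lam)


def _tendon_energy(params, lam):
    return cst.uniaxial_energy_tendon(cst.ShearerTendonParams(*params), lam)


def _tendon_to_unconstrained(params):
    ncm, fib, theta_o, gamma = params
    return np.array(
        [
            math.log(ncm),
            math.log(fib),
            float(logit(theta_o / (0.5 * math.pi))),
            math.log(gamma),
        ]
    )


def _tendon_from_unconstrained(theta):
    nu, eta, t, g = theta
    return np.array(
        [math.exp(nu), math.exp(eta), 0.5 * math.pi * float(expit(t)), math.exp(g)]
    )


def _tendon_log_jacobian(theta):
    nu, eta, t, g = theta
    p = float(expit(t))
    return nu + eta + g + math.log(0.5 * math.pi * p * (1.0 - p))


def _tendon_validate(params, lam_max=None):
    ncm, fib, theta_o, gamma = params
    ok = ncm > 0 and fib > 0 and 0.0 < theta_o < 0.5 * math.pi and gamma >= 0
    if lam_max is not None:
        ok = ok and gamma < lam_max - 1.0
    return ok


MODELS = {
    "st": ModelSpec(
        name="st",
        param_names=("ncm_modulus", "fibril_modulus", "a", "b"),
        transformed_names=("nu", "eta", "tau", "rho"),
        stress=_st_stress,
        energy=_recruitment_energy(_st_objects),
        to_unconstrained=_st_to_unconstrained,
        from_unconstrained=_st_from_unconstrained,
        log_jacobian=_sum_log_jacobian,
        validate=_st_validate,
    ),
    "gt": ModelSpec(
        name="gt",
        param_names=("ncm_modulus", "fibril_modulus", "a", "c", "b"),
        transformed_names=("nu", "eta", "tau", "kappa", "rho"),
        stress=_gt_stress,
        energy=_recruitment_energy(_gt_objects),
        to_unconstrained=_gt_to_unconstrained,
        from_unconstrained=_gt_from_unconstrained,
        log_jacobian=_sum_log_jacobian,
        validate=_gt_validate,
    ),
    "hgo": ModelSpec(
        name="hgo",
        param_names=("c_hgo", "k1", "k2"),
        transformed_names=("log_c_hgo", "log_k1", "log_k2"),
        stress=_hgo_stress,
        energy=_hgo_energy,
        to_unconstrained=_hgo_to_unconstrained,
        from_unconstrained=_hgo_from_unconstrained,
        log_jacobian=_sum_log_jacobian,
        validate=_hgo_validate,
    ),
    "tendon": ModelSpec(
        name="tendon",
        param_names=("ncm_modulus", "fibril_modulus", "theta_o", "gamma"),
        transformed_names=("nu", "eta", "logit_theta", "log_gamma"),
        stress=_tendon_stress,
        energy=_tendon_energy,
        to_unconstrained=_tendon_to_unconstrained,
        from_unconstrained=_tendon_from_unconstrained,
        log_jacobian=_tendon_log_jacobian,
        validate=_tendon_validate,
    ),
}


def get_model(name: str) -> ModelSpec:
    """Look up a registered model by name (case-insensitive)."""
    try:
        return MODELS[name.lower()]
    except KeyError:
        raise KeyError(f"unknown model {name!r}; choose from {sorted(MODELS)}") from None
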