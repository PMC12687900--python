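"""Shear-thinning blood rheology.

Blood in the microcirculation is markedly non-Newtonian: its apparent
viscosity falls by an order of magnitude between stasis and the shear
rates of ~10^6 1/s generated at an oscillating microbubble interface.
This module provides the five-parameter Carreau–Yasuda constitutive law

    eta(gdot) = eta_inf + (eta0 - eta_inf) * [1 + (lam*gdot)^a]^((n-1)/a)

which interpolates smoothly between the zero-shear plateau ``eta0`` and
the infinite-shear plateau ``eta_inf``, together with the scalar shear
rate invariant gdot = sqrt(2 D:D) built from the rate-of-deformation
tensor D. The rest of the simulator evaluates the law only at scalar
characteristic rates (bubble interface, vessel wall); the full viscous
stress tensor field is never assembled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CarreauYasudaParams",
    "ViscosityMode",
    "BLOOD_DEFAULT",
    "apparent_viscosity",
    "shear_rate_invariant",
    "interface_shear_rate",
]

# Shear rate above which [1 + x^a]^((n-1)/a) is evaluated in log space as
# x^(n-1); above this rate the dropped +1 perturbs the viscosity by
# < ~1e-12 relative (the thinning term is then < 1e-9 of eta_inf).
_LOG_SPACE_GDOT = 1.0e11


@dataclass(frozen=True)
class CarreauYasudaParams:
    """The five Carreau–Yasuda constants for blood.

    Parameters
    ----------
    eta0 : float
        Zero-shear-rate viscosity (Pa·s).
    eta_inf : float
        Infinite-shear-rate viscosity (Pa·s).
    lam : float
        Relaxation time (s); sets the shear rate ~1/lam where thinning begins.
    n : float
        Power index (dimensionless); n < 1 means shear-thinning.
    a : float
        Yasuda transition parameter (dimensionless); controls the sharpness
        of the crossover between the two plateaus.
    """

    eta0: float
    eta_inf: float
    lam: float
    n: float
    a: float

    def __post_init__(self) -> None:
        if not (self.eta0 > self.eta_inf > 0.0):
            raise ValueError("require eta0 > eta_inf > 0")
        if not (self.lam > 0.0 and self.a > 0.0):
            raise ValueError("require lam > 0 and a > 0")
        if not (0.0 < self.n < 1.0):
            raise ValueError("require 0 < n < 1 (shear-thinning regime)")


#: Literature blood parameters used as the default rheology.
BLOOD_DEFAULT = CarreauYasudaParams(
    eta0=0.0519, eta_inf=0.00476, lam=0.438, n=0.191, a=0.409
)


@dataclass(frozen=True)
class ViscosityMode:
    """Which viscosity law the simulator uses.

    ``kind='carreau_yasuda'`` evaluates the shear-thinning law with
    ``params``; ``kind='constant'`` uses the fixed hemodynamic value
    ``constant_value`` everywhere (the classical Newtonian simplification).
    """

    kind: str = "carreau_yasuda"
    constant_value: float = 0.0035
    params: CarreauYasudaParams = field(default=BLOOD_DEFAULT)

    def __post_init__(self) -> None:
        if self.kind not in ("carreau_yasuda", "constant"):
            raise ValueError(f"unknown viscosity mode {self.kind!r}")
        if self.kind == "constant" and not self.constant_value > 0.0:
            raise ValueError("constant viscosity must be positive")

    def viscosity(self, gamma_dot):
        """Apparent viscosity (Pa·s) at shear rate ``gamma_dot`` (1/s)."""
        if self.kind == "constant":
            return np.full_like(np.asarray(gamma_dot, dtype=float),
                                self.constant_value)[()]
        return apparent_viscosity(gamma_dot, self.params)


def apparent_viscosity(gamma_dot, params: CarreauYasudaParams = BLOOD_DEFAULT):
    """Carreau–Yasuda apparent viscosity.

    Parameters
    ----------
    gamma_dot : float or ndarray
        Shear rate (1/s), >= 0.
    params : CarreauYasudaParams
        Constitutive constants.

    Returns
    -------
    float or ndarray
        Viscosity in Pa·s, always in (eta_inf, eta0].
    """
    g = np.asarray(gamma_dot, dtype=float)
    if not np.all(np.isfinite(g)):
        raise ValueError("shear rate must be finite")
    if np.any(g < 0.0):
        raise ValueError("shear rate must be non-negative")

    lg = params.lam * g
    expo = (params.n - 1.0) / params.a
    with np.errstate(divide="ignore"):
        # log-space branch for very large rates avoids overflow in lg**a
        big = g > _LOG_SPACE_GDOT
        shape = np.where(
            big,
            np.exp(expo * params.a * np.log(np.where(big, lg, 1.0))),
            np.power(1.0 + np.power(np.where(big, 0.0, lg), params.a), expo),
        )
    eta = params.eta_inf + (params.eta0 - params.eta_inf) * shape
    return eta[()]


def shear_rate_invariant(D, sym_tol: float = 1e-8) -> float:
    """Scalar shear rate sqrt(2 D:D) from a rate-of-deformation tensor.

    ``D`` must be the symmetric part of the velocity gradient,
    D = (grad u + grad u^T)/2, in 1/s. For incompressible flow this
    invariant reduces to the usual simple-shear rate g for a velocity
    gradient with a single off-diagonal pair g/2.
    """
    D = np.asarray(D, dtype=float)
    if D.shape != (3, 3) or not np.all(np.isfinite(D)):
        raise ValueError("D must be a finite 3x3 tensor")
    scale = max(1.0, float(np.abs(D).max()))
    if np.abs(D - D.T).max() > sym_tol * scale:
        raise ValueError("D must be symmetric (pass the symmetrized gradient)")
    return float(math.sqrt(2.0 * np.tensordot(D, D)))


def interface_shear_rate(R, Rdot):
    """Characteristic shear rate 2*sqrt(3)*|Rdot|/R at a pulsating interface.

    This is the invariant sqrt(2 D:D) of the purely radial flow
    u_r = R^2 Rdot / r^2 evaluated at r = R, used to pick the viscosity
    in the bubbles' damping term.
    """
    return 2.0 * math.sqrt(3.0) * np.abs(Rdot) / np.asarray(R, dtype=float)
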