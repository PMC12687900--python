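"""Endothelial shape index and permeability from wall stress histories.

The biological endpoint of the simulator: wall shear stress and hoop
strain are combined into an effective stress tau = tau_ex - E eps, the
endothelial cell shape index follows the empirical regression

    SI(tau) = 0.38 exp(-0.79 tau) + 0.225 exp(-0.043 tau)      [tau in Pa]

(SI = 0.605 for an unstressed, rounded cell, decreasing toward 0 as cells
elongate under stress), and the hydraulic permeability of the leaky
junction follows

    K(SI) = pref * w^3 * (0.479 + 0.00593 exp(-14.75 SI)),
    pref  = 4e8 / (3 pi Rcell)

with w the junction half-width and Rcell the endothelial cell radius.
Because the regression is defined for non-negative shear stress, negative
effective stress is clamped to zero before the SI evaluation by default.
Summary metrics (pulse count, time-integrated excess permeability and the
dual/single enhancement ratio) are built so that the dimensional prefactor
cancels; absolute K values carry the configurable prefactor.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "EndotheliumParams",
    "PermeabilitySeries",
    "effective_stress",
    "shape_index",
    "permeability_K",
    "baseline_K",
    "excess_permeability",
    "pulse_count",
    "enhancement_ratio",
]

#: Unstressed shape index, SI(0) = 0.38 + 0.225.
SI_MAX = 0.605


@dataclass(frozen=True)
class EndotheliumParams:
    """Endothelial junction geometry and the stress-coupling modulus.

    Rcell: endothelial cell radius (m); w_half: half-width of the leaky
    junction (m); E: Young's modulus used in the effective-stress
    combination (Pa); clamp_negative_tau: clamp tau < 0 to 0 before the
    shape-index regression; prefactor: overrides the default
    4e8/(3 pi Rcell) permeability prefactor when set (all ratio metrics
    are invariant to it).
    """

    Rcell: float = 15.0e-6
    w_half: float = 20.0e-9
    E: float = 4.0e6
    clamp_negative_tau: bool = True
    prefactor: Optional[float] = None

    def __post_init__(self) -> None:
        if self.Rcell <= 0.0 or self.w_half <= 0.0:
            raise ValueError("Rcell and w_half must be positive")

    @property
    def K_prefactor(self) -> float:
        if self.prefactor is not None:
            return self.prefactor
        return 4.0e8 / (3.0 * math.pi * self.Rcell)


@dataclass
class PermeabilitySeries:
    """Effective stress, shape index and permeability on the (z, t) grid."""

    z: np.ndarray
    t: np.ndarray
    tau: np.ndarray
    SI: np.ndarray
    K: np.ndarray
    metrics: dict = field(default_factory=dict)

    def at_z(self, z0: float):
        i = int(np.argmin(np.abs(self.z - z0)))
        return i, {"tau": self.tau[i], "SI": self.SI[i], "K": self.K[i]}

    def to_frame(self):
        import pandas as pd

        nz, nt = self.K.shape
        return pd.DataFrame({
            "t_s": np.repeat(self.t, nz),
            "z_m": np.tile(self.z, nt),
            "tau_Pa": self.tau.T.ravel(),
            "SI": self.SI.T.ravel(),
            "K": self.K.T.ravel(),
        })


def effective_stress(tau_ex, eps, E: float, clamp: bool = True):
    """Effective endothelial stress tau = tau_ex - E eps.

    Returns the raw signed value; when ``clamp`` is true the value fed to
    the downstream shape-index regression should be max(tau, 0) — the
    helper :func:`shape_index` applies that via its ``clamp`` argument.
    """
    return np.asarray(tau_ex, dtype=float) - E * np.asarray(eps, dtype=float)


def shape_index(tau, clamp: bool = True):
    """Endothelial shape index from effective stress (Pa).

    Strictly decreasing in tau; SI(0) = 0.605 and SI -> 0 for large
    stress. Negative stresses are clamped to 0 when ``clamp`` is set;
    otherwise the regression is evaluated as written (with a warning),
    which extrapolates above 0.605.
    """
    tau = np.asarray(tau, dtype=float)
    if clamp:
        tau = np.maximum(tau, 0.0)
    elif np.any(tau < 0.0):
        warnings.warn("shape_index evaluated at negative stress "
                      "(regression extrapolation)", stacklevel=2)
    return (0.38 * np.exp(-0.79 * tau) + 0.225 * np.exp(-0.043 * tau))[()]


def permeability_K(SI, ep: EndotheliumParams = EndotheliumParams()):
    """Junction permeability K(SI) = pref w^3 (0.479 + 0.00593 e^(-14.75 SI)).

    Decreasing in SI: rounded cells (high SI) seal the junction, stressed
    elongated cells (low SI) open it. Units are set by the prefactor and
    w^3 and cancel in all ratio metrics.
    """
    SI = np.asarray(SI, dtype=float)
    return (ep.K_prefactor * ep.w_half**3
            * (0.479 + 0.00593 * np.exp(-14.75 * SI)))[()]


def baseline_K(ep: EndotheliumParams = EndotheliumParams()) -> float:
    """Permeability of the unstressed wall, K(SI(tau=0))."""
    return float(permeability_K(shape_index(0.0), ep))


def steady_window(t: np.ndarray, period: float, n_periods: int) -> np.ndarray:
    """Boolean mask selecting the last ``n_periods`` whole periods of ``t``."""
    span = t[-1] - t[0]
    if span < period:
        raise ValueError("series shorter than one acoustic period")
    n = min(n_periods, int(span / period))
    return t >= t[-1] - n * period


def excess_permeability(K: np.ndarray, t: np.ndarray, period: float,
                        ep: EndotheliumParams = EndotheliumParams(),
                        n_periods: Optional[int] = None):
    """Excess permeability above baseline and its steady-state integral.

    dK(t) = K(t) - K(SI(0)); the integral is trapezoidal over the last
    ``n_periods`` whole acoustic periods (all whole periods if None).

    Returns ``(dK_series, integral)``.
    """
    K = np.asarray(K, dtype=float)
    dK = K - baseline_K(ep)
    mask = steady_window(t, period, n_periods or np.inf)
    integral = float(np.trapezoid(dK[mask], t[mask]))
    return dK, integral


def pulse_count(K: np.ndarray, t: np.ndarray,
                threshold_frac: float = 0.1,
                ep: EndotheliumParams = EndotheliumParams()) -> float:
    """Permeability pulses per second: upward threshold crossings of K(t).

    The threshold is K_baseline + threshold_frac * max(dK) over the
    supplied (steady-state) window; a flat series yields 0.
    """
    K = np.asarray(K, dtype=float)
    dK = K - baseline_K(ep)
    peak = float(dK.max(initial=0.0))
    if peak <= 0.0:
        return 0.0
    thr = threshold_frac * peak
    above = dK > thr
    crossings = int(np.count_nonzero(~above[:-1] & above[1:]))
    return crossings / float(t[-1] - t[0])


def enhancement_ratio(dual_integral: float, single_integral: float) -> float:
    """Dual/single ratio of time-integrated excess permeability.

    Both integrals must come from the same wall observation point, drive
    and steady-state window length; the permeability prefactor and w^3
    cancel. A zero single-bubble integral makes the ratio undefined.
    """
    if single_integral == 0.0:
        raise ZeroDivisionError("single-bubble excess-permeability integral "
                                "is zero: enhancement ratio undefined")
    return float(dual_integral) / float(single_integral)
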