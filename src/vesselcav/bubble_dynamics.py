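"""Coupled radial dynamics of one or two acoustically driven microbubbles.

The model is the incompressible Rayleigh–Plesset system extended with the
standard radiation-coupling term for a bubble pair at centre distance d:

    R_i R''_i + 3/2 R'_i^2 + (1/d) d/dt(R_j^2 R'_j)
        = (1/rho_f) [ p_g,i + p_v - p_0 + P_d sin(2 pi f t + phase)
                      - 2 sigma_g / R_i - 4 eta(gdot_i) R'_i / R_i ]

with polytropic gas pressure p_g = p_g0 (R_0/R)^(3 kappa), surface tension
sigma_g, and viscous damping evaluated at the interface characteristic
shear rate gdot_i = 2 sqrt(3) |R'_i| / R_i through either a constant or a
Carreau–Yasuda viscosity. The coupling term contains R''_j, so each step
solves the 2x2 linear system in (R''_1, R''_2) exactly. Bubbles are
shell-free and held at fixed positions on the vessel axis; the vessel wall
is one-way coupled downstream and does not feed back on the radial motion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, TYPE_CHECKING

import numpy as np
from scipy.integrate import solve_ivp

from .rheology import ViscosityMode, interface_shear_rate

if TYPE_CHECKING:  # pragma: no cover
    from .config import ScenarioConfig

__all__ = [
    "GasLiquidParams",
    "AcousticDrive",
    "BubbleConfig",
    "Trajectory",
    "initial_gas_pressure",
    "gas_pressure",
    "natural_frequency",
    "coupled_accelerations",
    "simulate",
    "secondary_bjerknes",
    "CollapseError",
]


class CollapseError(RuntimeError):
    """Raised when a bubble radius falls below the stable-cavitation guard."""


@dataclass(frozen=True)
class GasLiquidParams:
    """Gas and liquid constants.

    kappa: polytropic exponent of the bubble gas (1 = isothermal,
    gamma = adiabatic); pv: vapour pressure (Pa); sigma_g: gas-liquid
    surface tension (N/m); p0: ambient static pressure (Pa); rho_f:
    liquid (blood) density (kg/m^3).
    """

    kappa: float = 1.07
    pv: float = 2330.0
    sigma_g: float = 0.056
    p0: float = 1.013e5
    rho_f: float = 1059.0

    def __post_init__(self) -> None:
        if min(self.kappa, self.pv, self.sigma_g, self.p0, self.rho_f) <= 0:
            raise ValueError("all gas/liquid parameters must be positive")
        if self.kappa < 1.0:
            raise ValueError("polytropic exponent must be >= 1")


@dataclass(frozen=True)
class AcousticDrive:
    """Sinusoidal far-field drive p0 - Pd sin(2 pi f t + phase)."""

    Pd: float = 0.3e5
    f: float = 1.5e6
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.Pd < 0.0 or self.f <= 0.0:
            raise ValueError("require Pd >= 0 and f > 0")

    @property
    def period(self) -> float:
        return 1.0 / self.f


@dataclass(frozen=True)
class BubbleConfig:
    """One or two bubbles on the vessel axis.

    Bubble 1 sits at z = -d/2, bubble 2 (if present) at z = +d/2.
    Single-bubble mode is selected by leaving ``R20`` unset; bubble 1
    keeps its position at z = -d/2.
    """

    R10: float = 2.0e-6
    R20: Optional[float] = None
    d: float = 10.0e-6

    def __post_init__(self) -> None:
        if self.R10 <= 0.0:
            raise ValueError("R10 must be positive")
        if self.R20 is not None:
            if self.R20 <= 0.0:
                raise ValueError("R20 must be positive")
            if self.d <= self.R10 + self.R20:
                raise ValueError("bubbles overlap: require d > R10 + R20")

    @property
    def n_bubbles(self) -> int:
        return 1 if self.R20 is None else 2

    @property
    def radii(self) -> np.ndarray:
        if self.R20 is None:
            return np.array([self.R10])
        return np.array([self.R10, self.R20])

    @property
    def positions(self) -> np.ndarray:
        """Axial positions (m) of the bubble centres."""
        if self.R20 is None:
            return np.array([-0.5 * self.d])
        return np.array([-0.5 * self.d, 0.5 * self.d])


@dataclass
class Trajectory:
    """Time series of the radial bubble motion on a uniform output grid.

    ``R``, ``Rdot``, ``Rddot`` have shape (n_bubbles, nt); ``positions``
    holds the fixed axial bubble coordinates. ``collapsed`` flags an
    early inertial-regime exit (the arrays then cover only the partial
    run up to the collapse guard).
    """

    t: np.ndarray
    R: np.ndarray
    Rdot: np.ndarray
    Rddot: np.ndarray
    positions: np.ndarray
    collapsed: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def n_bubbles(self) -> int:
        return self.R.shape[0]

    @property
    def V(self) -> np.ndarray:
        return 4.0 * np.pi / 3.0 * self.R**3

    @property
    def Vdot(self) -> np.ndarray:
        return 4.0 * np.pi * self.R**2 * self.Rdot

    def to_frame(self, d: Optional[float] = None,
                 rho_f: Optional[float] = None):
        """Columnar view; adds the pair interaction force when possible."""
        import pandas as pd

        cols = {"t_s": self.t}
        for i in range(self.n_bubbles):
            k = i + 1
            cols[f"R{k}_m"] = self.R[i]
            cols[f"R{k}dot_m_s"] = self.Rdot[i]
        for i in range(self.n_bubbles):
            cols[f"V{i + 1}_m3"] = self.V[i]
        if self.n_bubbles == 2 and d is not None and rho_f is not None:
            cols["FSB_N"] = secondary_bjerknes(self, d, rho_f)[0]
        return pd.DataFrame(cols)


def initial_gas_pressure(R0: float, glp: GasLiquidParams) -> float:
    """Equilibrium gas pressure p0 + 2 sigma_g / R0 - pv inside the bubble."""
    if R0 <= 0.0:
        raise ValueError("R0 must be positive")
    pg0 = glp.p0 + 2.0 * glp.sigma_g / R0 - glp.pv
    if pg0 <= 0.0:
        raise ValueError("unphysical bubble: non-positive equilibrium gas pressure")
    return pg0


def gas_pressure(R, R0: float, pg0: float, kappa: float):
    """Polytropic gas pressure pg0 (R0/R)^(3 kappa)."""
    R = np.asarray(R, dtype=float)
    if np.any(R <= 0.0):
        raise ValueError("R must be positive")
    return (pg0 * (R0 / R) ** (3.0 * kappa))[()]


def natural_frequency(R0: float, glp: GasLiquidParams) -> float:
    """Linear (Minnaert-type) resonance frequency with surface tension.

    f0 = (1 / 2 pi R0) sqrt[(3 kappa pg0 - 2 sigma_g / R0) / rho_f], the
    small-oscillation eigenfrequency of the radial dynamics about R0.
    """
    pg0 = initial_gas_pressure(R0, glp)
    radicand = (3.0 * glp.kappa * pg0 - 2.0 * glp.sigma_g / R0) / glp.rho_f
    if radicand <= 0.0:
        raise ValueError("surface tension dominates: no real resonance")
    return math.sqrt(radicand) / (2.0 * math.pi * R0)


def _liquid_rhs(R, Rdot, t, R0, pg0, drive: AcousticDrive,
                glp: GasLiquidParams, mode: ViscosityMode):
    """Per-bubble pressure RHS divided by rho_f. Broadcasts over time."""
    pg = pg0 * (R0 / R) ** (3.0 * glp.kappa)
    eta = mode.viscosity(interface_shear_rate(R, Rdot))
    pa = drive.Pd * np.sin(2.0 * np.pi * drive.f * t + drive.phase)
    return (pg + glp.pv - glp.p0 + pa
            - 2.0 * glp.sigma_g / R - 4.0 * eta * Rdot / R) / glp.rho_f


def coupled_accelerations(R, Rdot, t, bubbles: BubbleConfig,
                          drive: AcousticDrive, glp: GasLiquidParams,
                          mode: ViscosityMode,
                          pg0: Optional[np.ndarray] = None) -> np.ndarray:
    """Radial accelerations R'' of the (possibly coupled) bubble system.

    ``R`` and ``Rdot`` have shape (n_bubbles,) or (n_bubbles, nt); the
    2x2 linear system arising from the mutual radiation coupling is
    solved in closed form. Returns an array of the same shape as ``R``.
    """
    R = np.asarray(R, dtype=float)
    Rdot = np.asarray(Rdot, dtype=float)
    if np.any(R <= 0.0):
        raise CollapseError("non-positive bubble radius")
    R0s = bubbles.radii
    if pg0 is None:
        pg0 = np.array([initial_gas_pressure(r0, glp) for r0 in R0s])
    while R0s.ndim < R.ndim:
        R0s = R0s[..., None]
        pg0 = np.asarray(pg0)[..., None]

    rhs = _liquid_rhs(R, Rdot, t, R0s, pg0, drive, glp, mode)
    if bubbles.n_bubbles == 1:
        return (rhs - 1.5 * Rdot**2) / R

    d = bubbles.d
    b = np.empty_like(R)
    b[0] = rhs[0] - 1.5 * Rdot[0] ** 2 - (2.0 / d) * R[1] * Rdot[1] ** 2
    b[1] = rhs[1] - 1.5 * Rdot[1] ** 2 - (2.0 / d) * R[0] * Rdot[0] ** 2
    # [[R1, R2^2/d], [R1^2/d, R2]] [R1'', R2'']^T = b
    a12 = R[1] ** 2 / d
    a21 = R[0] ** 2 / d
    det = R[0] * R[1] - a12 * a21
    # det = R1 R2 (1 - R1 R2 / d^2) > 0 whenever d > R1 + R2
    out = np.empty_like(R)
    out[0] = (b[0] * R[1] - a12 * b[1]) / det
    out[1] = (R[0] * b[1] - a21 * b[0]) / det
    return out


def simulate(cfg: "ScenarioConfig", t_end: Optional[float] = None,
             output_dt: Optional[float] = None) -> Trajectory:
    """Integrate the bubble system from a quiescent start.

    Initial conditions are R_i(0) = R_i0, R'_i(0) = 0. Integration uses
    an adaptive stiff (Radau) method at the tolerances in
    ``cfg.integration``; the returned :class:`Trajectory` is sampled on
    a uniform grid of ``samples_per_cycle`` points per acoustic period.
    A radius falling below ``r_min_frac * R_i0`` terminates the run and
    flags the trajectory as an inertial-regime exit.
    """
    bub, drive, glp, mode = cfg.bubbles, cfg.drive, cfg.gas_liquid, cfg.rheology
    ictl = cfg.integration
    if t_end is None:
        t_end = ictl.t_end_cycles * drive.period
    if output_dt is None:
        output_dt = drive.period / ictl.samples_per_cycle
    if t_end <= 0.0:
        raise ValueError("t_end must be positive")

    nb = bub.n_bubbles
    R0s = bub.radii
    pg0 = np.array([initial_gas_pressure(r0, glp) for r0 in R0s])
    r_min = ictl.r_min_frac * R0s

    # implicit-solver trial values can probe R below the collapse guard
    # (even <= 0) inside a step; clip there so the terminal event, not a
    # domain error, ends the run.
    r_floor = 1e-3 * r_min

    def rhs(t, y):
        R, Rdot = np.maximum(y[:nb], r_floor), y[nb:]
        acc = coupled_accelerations(R, Rdot, t, bub, drive, glp, mode, pg0)
        return np.concatenate([Rdot, acc])

    def collapse(t, y):
        return float(np.min(y[:nb] - r_min))

    collapse.terminal = True
    collapse.direction = -1

    y0 = np.concatenate([R0s, np.zeros(nb)])
    n_out = int(round(t_end / output_dt)) + 1
    t_eval = np.linspace(0.0, t_end, n_out)
    atol = np.concatenate([np.full(nb, ictl.atol_R),
                           np.full(nb, ictl.atol_Rdot)])
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="Radau",
                    t_eval=t_eval, rtol=ictl.rtol, atol=atol,
                    events=collapse, dense_output=False)
    if sol.status == -1:
        raise RuntimeError(f"bubble integration failed: {sol.message}")

    collapsed = sol.status == 1
    t = sol.t
    R = sol.y[:nb]
    Rdot = sol.y[nb:]
    Rddot = coupled_accelerations(R, Rdot, t, bub, drive, glp, mode, pg0)
    meta = {"nfev": sol.nfev, "njev": sol.njev,
            "integrator": "Radau", "rtol": ictl.rtol}
    if collapsed:
        meta["exit"] = "inertial-regime exit (collapse guard)"
    return Trajectory(t=t, R=R, Rdot=Rdot, Rddot=Rddot,
                      positions=bub.positions, collapsed=collapsed, meta=meta)


def secondary_bjerknes(traj: Trajectory, d: float, rho_f: float,
                       period: Optional[float] = None):
    """Secondary Bjerknes interaction force between the bubble pair.

    F(t) = -rho_f / (4 pi d^2) Vdot_1 Vdot_2; a negative value means
    mutual attraction. The time average uses trapezoidal quadrature over
    the largest whole number of acoustic periods that fits at the end of
    the series (or the full series if ``period`` is None).

    Returns ``(F_series, F_mean)``.
    """
    if traj.n_bubbles != 2:
        raise ValueError("secondary Bjerknes force requires two bubbles")
    Vdot = traj.Vdot
    F = -rho_f / (4.0 * np.pi * d**2) * Vdot[0] * Vdot[1]
    t = traj.t
    if period is not None:
        span = t[-1] - t[0]
        n_per = int(span / period)
        if n_per < 1:
            raise ValueError("series shorter than one acoustic period")
        mask = t >= t[-1] - n_per * period
        t, F_win = t[mask], F[mask]
    else:
        F_win = F
    F_mean = float(np.trapezoid(F_win, t) / (t[-1] - t[0]))
    return F, F_mean
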