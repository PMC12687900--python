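"""Microstreaming wall stresses and the elastic response of the vessel wall.

The flow a pulsating bubble drives in the surrounding liquid is modelled as
a free-space potential source at the bubble centre: u(x) = sum_i R_i^2 R'_i
(x - x_i)/|x - x_i|^3. Wall quantities are evaluated on an axial grid along
the inner vessel surface r = RV:

* shear stress tau_ex = eta(gdot_wall) du_z/dr, with the radial derivative
  of the axial source velocity taken analytically at the wall;
* normal stress from the unsteady-Bernoulli pressure of the source field,
  sigma_n = rho_f sum_i d/dt(R_i^2 R'_i)/s_i - rho_f |u|^2 / 2
  (positive = outward push, negative = suction / invagination);
* wall displacement from a per-point lumped spring-mass-damper element,
  rho_s h w'' + c w' + k_w w = sigma_n, with thin-shell hoop stiffness
  k_w = E h / RV^2 and damping c = 2 zeta sqrt(k_w rho_s h); the hoop
  strain is eps = w / RV.

No image corrections are applied for the cylindrical wall, and the wall
motion does not feed back on the bubbles: wall fields are pure
post-processing of a :class:`~vesselcav.bubble_dynamics.Trajectory`.
This keeps orderings and parameter trends while underestimating the
confinement effects a full fluid-structure solution would capture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bubble_dynamics import Trajectory
from .rheology import ViscosityMode

__all__ = [
    "VesselConfig",
    "WallSeries",
    "induced_velocity",
    "wall_shear_stress",
    "wall_normal_stress",
    "wall_response",
    "compute_wall_series",
]


@dataclass(frozen=True)
class VesselConfig:
    """Microvessel geometry and wall material.

    RV: inner radius (m); L: segment length (m); rho_s: wall density
    (kg/m^3); E: Young's modulus (Pa); nu: Poisson ratio; h: wall
    thickness (m); zeta: damping ratio of the lumped wall element;
    plane_strain: use E/(1-nu^2) in the hoop stiffness; n_axial: number
    of axial grid points over [-L/2, L/2].
    """

    RV: float = 5.0e-6
    L: float = 40.0e-6
    rho_s: float = 1049.0
    E: float = 4.0e6
    nu: float = 0.49
    h: float = 1.0e-6
    zeta: float = 0.1
    plane_strain: bool = False
    n_axial: int = 81

    def __post_init__(self) -> None:
        if min(self.RV, self.L, self.E, self.h, self.rho_s) <= 0:
            raise ValueError("geometry and material constants must be positive")
        if not 0.0 < self.nu < 0.5:
            raise ValueError("Poisson ratio must lie in (0, 0.5)")
        if self.zeta < 0.0:
            raise ValueError("damping ratio must be non-negative")
        if self.n_axial < 3:
            raise ValueError("axial grid needs at least 3 points")

    @property
    def axial_grid(self) -> np.ndarray:
        return np.linspace(-0.5 * self.L, 0.5 * self.L, self.n_axial)

    @property
    def hoop_stiffness(self) -> float:
        """Lumped wall stiffness k_w = E h / RV^2 (Pa/m), per unit area."""
        E = self.E / (1.0 - self.nu**2) if self.plane_strain else self.E
        return E * self.h / self.RV**2


@dataclass
class WallSeries:
    """Wall-line fields on the (z, t) grid.

    Arrays are shaped (n_axial, nt). ``sigma_n`` < 0 means suction
    (invagination of the wall toward the lumen).
    """

    z: np.ndarray
    t: np.ndarray
    tau_ex: np.ndarray
    sigma_n: np.ndarray
    w_d: np.ndarray
    eps: np.ndarray
    meta: dict = field(default_factory=dict)

    def at_z(self, z0: float):
        """Index of the grid point nearest ``z0`` and the field slices there."""
        i = int(np.argmin(np.abs(self.z - z0)))
        return i, {
            "tau_ex": self.tau_ex[i],
            "sigma_n": self.sigma_n[i],
            "w_d": self.w_d[i],
            "eps": self.eps[i],
        }

    def to_frame(self):
        import pandas as pd

        nz, nt = self.tau_ex.shape
        return pd.DataFrame({
            "t_s": np.repeat(self.t, nz),
            "z_m": np.tile(self.z, nt),
            "tau_ex_Pa": self.tau_ex.T.ravel(),
            "sigma_n_Pa": self.sigma_n.T.ravel(),
            "w_d_m": self.w_d.T.ravel(),
            "eps": self.eps.T.ravel(),
        })


def induced_velocity(point, R, Rdot, positions):
    """Liquid velocity (u_r, u_z) at ``point`` = (r, z) from the sources.

    ``R``, ``Rdot`` and ``positions`` are per-bubble arrays; the point
    must lie outside every bubble. Superposition of free-space pulsating
    sources of strength R_i^2 R'_i.
    """
    r, z = point
    R = np.asarray(R, dtype=float)
    Rdot = np.asarray(Rdot, dtype=float)
    positions = np.asarray(positions, dtype=float)
    dz = z - positions
    s = np.sqrt(r**2 + dz**2)
    if np.any(s <= R):
        raise ValueError("observation point lies inside a bubble")
    m = R**2 * Rdot
    u_r = np.sum(m * r / s**3)
    u_z = np.sum(m * dz / s**3)
    return np.array([u_r, u_z])


def _wall_geometry(traj: Trajectory, vcfg: VesselConfig):
    """Distances and offsets from each bubble to each wall grid point."""
    z = vcfg.axial_grid
    dz = z[:, None] - traj.positions[None, :]        # (nz, nb)
    s = np.sqrt(vcfg.RV**2 + dz**2)
    return z, dz, s


def wall_shear_stress(traj: Trajectory, vcfg: VesselConfig,
                      mode: ViscosityMode) -> np.ndarray:
    """Signed wall shear stress tau_ex(z, t) = eta(gdot) du_z/dr at r = RV.

    The radial derivative of the axial source velocity is analytic:
    du_z/dr = -3 m_i (z - z_i) r / s_i^5 summed over bubbles, with
    m_i = R_i^2 R'_i. The viscosity is evaluated at |du_z/dr|.
    """
    z, dz, s = _wall_geometry(traj, vcfg)
    m = traj.R**2 * traj.Rdot                        # (nb, nt)
    geom = -3.0 * dz * vcfg.RV / s**5                # (nz, nb)
    dudr = geom @ m                                  # (nz, nt)
    eta = mode.viscosity(np.abs(dudr))
    return eta * dudr


def wall_normal_stress(traj: Trajectory, vcfg: VesselConfig,
                       rho_f: float) -> np.ndarray:
    """Unsteady-Bernoulli normal stress sigma_n(z, t) at the wall."""
    z, dz, s = _wall_geometry(traj, vcfg)
    mdot = 2.0 * traj.R * traj.Rdot**2 + traj.R**2 * traj.Rddot  # (nb, nt)
    unsteady = (1.0 / s) @ mdot                       # (nz, nt)
    m = traj.R**2 * traj.Rdot
    u_r = (vcfg.RV / s**3) @ m
    u_z = (dz / s**3) @ m
    return rho_f * unsteady - 0.5 * rho_f * (u_r**2 + u_z**2)


def wall_response(sigma_n: np.ndarray, t: np.ndarray,
                  vcfg: VesselConfig):
    """Radial wall displacement and hoop strain from the normal-stress load.

    Integrates, independently at every axial point, the lumped element

        rho_s h w'' + c w' + k_w w = sigma_n(t)

    from quiescent initial conditions, with k_w = E h / RV^2 and
    c = 2 zeta sqrt(k_w rho_s h). The load is treated as piecewise
    linear between samples and the LTI system is advanced with the
    exact matrix-exponential propagator for that forcing, so the only
    discretisation error is the piecewise-linear rendering of the load.

    Returns ``(w_d, eps)`` with the same shape as ``sigma_n``.
    """
    sigma_n = np.atleast_2d(np.asarray(sigma_n, dtype=float))
    if not np.all(np.isfinite(sigma_n)):
        raise ValueError("normal-stress load must be finite")
    m = vcfg.rho_s * vcfg.h
    k = vcfg.hoop_stiffness
    if k <= 0.0 or m <= 0.0:
        raise ValueError("non-positive wall stiffness or mass")
    c = 2.0 * vcfg.zeta * np.sqrt(k * m)

    dt = float(t[1] - t[0])
    if not np.allclose(np.diff(t), dt, rtol=1e-9, atol=0.0):
        raise ValueError("wall_response requires a uniform time grid")

    # state x = (w, wdot); x' = A x + B f(t), f piecewise linear.
    A = np.array([[0.0, 1.0], [-k / m, -c / m]])
    B = np.array([0.0, 1.0 / m])
    from scipy.linalg import expm

    Ainv = np.linalg.inv(A)
    Phi = expm(A * dt)
    I2 = np.eye(2)
    # exact holds for f(t) = f0 + (f1 - f0) t/dt over one step:
    #   x1 = Phi x0 + G0 f0 + G1 (f1 - f0)
    G0 = Ainv @ (Phi - I2) @ B
    G1 = Ainv @ ((Ainv @ (Phi - I2)) / dt - I2) @ B

    nz, nt = sigma_n.shape
    w = np.zeros((nz, nt))
    wd = np.zeros(nz)
    wv = np.zeros(nz)
    for j in range(nt - 1):
        f0 = sigma_n[:, j]
        df = sigma_n[:, j + 1] - f0
        nw = (Phi[0, 0] * wd + Phi[0, 1] * wv + G0[0] * f0 + G1[0] * df)
        nv = (Phi[1, 0] * wd + Phi[1, 1] * wv + G0[1] * f0 + G1[1] * df)
        wd, wv = nw, nv
        w[:, j + 1] = wd
    eps = w / vcfg.RV
    return w, eps


def compute_wall_series(traj: Trajectory, vcfg: VesselConfig,
                        mode: ViscosityMode, rho_f: float) -> WallSeries:
    """Full wall-line post-processing chain for one trajectory."""
    tau = wall_shear_stress(traj, vcfg, mode)
    sig = wall_normal_stress(traj, vcfg, rho_f)
    w, eps = wall_response(sig, traj.t, vcfg)
    return WallSeries(z=vcfg.axial_grid, t=traj.t, tau_ex=tau,
                      sigma_n=sig, w_d=w, eps=eps,
                      meta={"h": vcfg.h, "zeta": vcfg.zeta,
                            "k_w": vcfg.hoop_stiffness,
                            "plane_strain": vcfg.plane_strain})
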