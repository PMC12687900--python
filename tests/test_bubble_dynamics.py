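import dataclasses

import numpy as np
import pytest

import vesselcav as vc
from vesselcav.bubble_dynamics import (
    AcousticDrive,
    BubbleConfig,
    GasLiquidParams,
    Trajectory,
    coupled_accelerations,
    gas_pressure,
    initial_gas_pressure,
    natural_frequency,
    secondary_bjerknes,
    simulate,
)
from vesselcav.rheology import ViscosityMode, apparent_viscosity, interface_shear_rate

GLP = GasLiquidParams()


class TestGasLaw:
    def test_initial_gas_pressure_reference(self):
        assert initial_gas_pressure(2e-6, GLP) == pytest.approx(154_970.0)

    def test_surface_tension_free_limit(self):
        glp = dataclasses.replace(GLP, sigma_g=1e-30, pv=1e-30)
        assert initial_gas_pressure(2e-6, glp) == pytest.approx(GLP.p0)

    def test_laplace_term_linear_in_inverse_radius(self):
        excess = lambda R0: initial_gas_pressure(R0, GLP) - GLP.p0 + GLP.pv
        assert excess(1e-6) == pytest.approx(2 * excess(2e-6), rel=1e-12)

    def test_unphysical_bubble_rejected(self):
        glp = dataclasses.replace(GLP, pv=2e5)  # pv exceeds p0 + Laplace
        with pytest.raises(ValueError):
            initial_gas_pressure(2e-6, glp)

    def test_gas_pressure_polytropic(self):
        pg0 = initial_gas_pressure(2e-6, GLP)
        assert gas_pressure(2e-6, 2e-6, pg0, 1.07) == pytest.approx(pg0)
        assert gas_pressure(1e-6, 2e-6, pg0, 1.07) == pytest.approx(
            pg0 * 2 ** 3.21, rel=1e-12)
        assert gas_pressure(1.0, 2e-6, pg0, 1.07) < 1e-10
        R = np.linspace(0.5e-6, 5e-6, 50)
        assert np.all(np.diff(gas_pressure(R, 2e-6, pg0, 1.07)) < 0)
        with pytest.raises(ValueError):
            gas_pressure(-1e-6, 2e-6, pg0, 1.07)


class TestNaturalFrequency:
    def test_classical_minnaert_limit(self):
        glp = dataclasses.replace(GLP, sigma_g=1e-30, pv=1e-30)
        R0 = 2e-6
        expected = np.sqrt(3 * glp.kappa * glp.p0 / glp.rho_f) / (2 * np.pi * R0)
        assert natural_frequency(R0, glp) == pytest.approx(expected, rel=1e-6)
        # 1/R0 scaling without surface tension
        assert natural_frequency(R0 / 2, glp) == pytest.approx(
            2 * natural_frequency(R0, glp), rel=1e-6)

    def test_matches_linearized_stiffness(self):
        # omega0^2 = -f'(R0) / (rho R0) with f the static pressure balance,
        # derivative taken by central differences (independent of the formula)
        R0 = 2e-6
        pg0 = initial_gas_pressure(R0, GLP)
        h = R0 * 1e-6

        def balance(R):
            return gas_pressure(R, R0, pg0, GLP.kappa) + GLP.pv - GLP.p0 \
                - 2 * GLP.sigma_g / R

        fprime = (balance(R0 + h) - balance(R0 - h)) / (2 * h)
        f0 = np.sqrt(-fprime / (GLP.rho_f * R0)) / (2 * np.pi)
        assert natural_frequency(R0, GLP) == pytest.approx(f0, rel=1e-6)


class TestBubbleConfig:
    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            BubbleConfig(R10=6e-6, R20=5e-6, d=10e-6)

    def test_positions(self):
        assert np.allclose(BubbleConfig(d=10e-6, R20=2e-6).positions,
                           [-5e-6, 5e-6])
        assert np.allclose(BubbleConfig(d=10e-6).positions, [-5e-6])


class TestCoupledAccelerations:
    MODE = ViscosityMode(kind="constant", constant_value=0.0035)

    def test_equilibrium_is_fixed_point(self):
        bub = BubbleConfig(R10=2e-6, R20=3e-6, d=12e-6)
        drive = AcousticDrive(Pd=0.0)
        acc = coupled_accelerations(bub.radii, np.zeros(2), 0.0, bub,
                                    drive, GLP, self.MODE)
        # zero up to float cancellation in the ~1e5 Pa pressure balance
        assert np.allclose(acc, 0.0, atol=1e-5)

    def test_large_spacing_decouples(self):
        rng = np.random.default_rng(7)
        R = np.array([2.2e-6, 2.8e-6])
        Rdot = rng.normal(scale=1.0, size=2)
        drive = AcousticDrive()
        far = BubbleConfig(R10=2e-6, R20=3e-6, d=1e6)
        acc_far = coupled_accelerations(R, Rdot, 1e-7, far, drive, GLP, self.MODE)
        for i in range(2):
            solo = BubbleConfig(R10=far.radii[i])
            acc_solo = coupled_accelerations(R[i:i + 1], Rdot[i:i + 1], 1e-7,
                                             solo, drive, GLP, self.MODE)
            assert acc_far[i] == pytest.approx(acc_solo[0], rel=1e-8)

    @pytest.mark.parametrize("mode", [
        ViscosityMode(kind="constant", constant_value=0.0035),
        ViscosityMode(kind="carreau_yasuda"),
    ])
    def test_agrees_with_symbolic_assembly(self, mode):
        """Closed-form 2x2 solve vs an independent sympy assembly."""
        import sympy as sp

        bub = BubbleConfig(R10=2e-6, R20=3e-6, d=12e-6)
        drive = AcousticDrive()
        rng = np.random.default_rng(42)
        for _ in range(5):
            R = bub.radii * rng.uniform(0.7, 1.3, size=2)
            Rdot = rng.normal(scale=2.0, size=2)
            t = rng.uniform(0.0, 1e-6)
            got = coupled_accelerations(R, Rdot, t, bub, drive, GLP, mode)

            a1, a2 = sp.symbols("a1 a2")
            eqs = []
            for i, j in ((0, 1), (1, 0)):
                pg0 = GLP.p0 + 2 * GLP.sigma_g / bub.radii[i] - GLP.pv
                pg = pg0 * (bub.radii[i] / R[i]) ** (3 * GLP.kappa)
                eta = float(mode.viscosity(interface_shear_rate(R[i], Rdot[i])))
                rhs = (pg + GLP.pv - GLP.p0
                       + drive.Pd * np.sin(2 * np.pi * drive.f * t)
                       - 2 * GLP.sigma_g / R[i]
                       - 4 * eta * Rdot[i] / R[i]) / GLP.rho_f
                acc_i, acc_j = (a1, a2) if i == 0 else (a2, a1)
                eqs.append(sp.Eq(
                    R[i] * acc_i + sp.Rational(3, 2) * Rdot[i] ** 2
                    + (2 * R[j] * Rdot[j] ** 2 + R[j] ** 2 * acc_j) / bub.d,
                    rhs))
            sol = sp.solve(eqs, (a1, a2))
            expected = np.array([float(sol[a1]), float(sol[a2])])
            assert np.allclose(got, expected, rtol=1e-10)


class TestSimulate:
    def test_quiescent_without_drive(self, base_cfg):
        cfg = base_cfg.replace(drive=AcousticDrive(Pd=0.0, f=1.5e6))
        traj = simulate(cfg)
        assert np.abs(traj.R / 2e-6 - 1.0).max() < 1e-7
        assert np.abs(traj.Rdot).max() < 1e-4

    def test_equal_bubbles_identical_trajectories(self, dual_run):
        traj = dual_run.trajectory
        assert np.abs(traj.R[0] - traj.R[1]).max() <= 1e-12 * 2e-6

    def test_output_grid_uniform(self, dual_run, base_cfg):
        t = dual_run.trajectory.t
        ictl = base_cfg.integration
        assert len(t) == int(ictl.t_end_cycles * ictl.samples_per_cycle) + 1
        assert np.allclose(np.diff(t), t[1] - t[0], rtol=1e-9)

    def test_volume_rate_consistency(self, dual_run):
        # dV/dt by central differences matches 4 pi R^2 Rdot
        traj = dual_run.trajectory
        dVdt = np.gradient(traj.V[0], traj.t)
        scale = np.abs(traj.Vdot[0]).max()
        err = np.abs(dVdt[2:-2] - traj.Vdot[0][2:-2]).max() / scale
        assert err < 2e-3

    def test_collapse_guard_flags_partial_run(self, base_cfg):
        cfg = base_cfg.single_bubble().replace(
            drive=AcousticDrive(Pd=5e5, f=1.5e6))
        cfg = cfg.replace(integration=dataclasses.replace(
            cfg.integration, t_end_cycles=5.0))
        traj = simulate(cfg)
        assert traj.collapsed
        assert "inertial" in traj.meta["exit"]
        assert traj.t[-1] < 5.0 / 1.5e6

    def test_rheology_changes_the_motion(self, single_run, single_const_run):
        dev = np.abs(single_run.trajectory.R - single_const_run.trajectory.R)
        assert dev.max() / 2e-6 > 1e-3


class TestSecondaryBjerknes:
    def test_requires_two_bubbles(self, single_run):
        with pytest.raises(ValueError):
            secondary_bjerknes(single_run.trajectory, 10e-6, 1059.0)

    def test_static_bubbles_no_force(self):
        t = np.linspace(0, 1e-5, 100)
        R = np.full((2, t.size), 2e-6)
        z = np.zeros((2, t.size))
        traj = Trajectory(t=t, R=R, Rdot=z, Rddot=z,
                          positions=np.array([-5e-6, 5e-6]))
        F, Fmean = secondary_bjerknes(traj, 10e-6, 1059.0)
        assert np.all(F == 0.0) and Fmean == 0.0

    def test_in_phase_pair_attracts(self, dual_run, base_cfg):
        F, Fmean = secondary_bjerknes(dual_run.trajectory, 10e-6, 1059.0,
                                      period=base_cfg.drive.period)
        assert np.all(F <= 0.0)  # identical in-phase: Vdot1*Vdot2 >= 0
        assert Fmean < 0.0

    def test_average_matches_independent_quadrature(self, dual_run, base_cfg):
        traj = dual_run.trajectory
        d, rho = 10e-6, 1059.0
        F, Fmean = secondary_bjerknes(traj, d, rho, period=base_cfg.drive.period)
        # manual trapezoid over the same trailing whole-period window
        t = traj.t
        n_per = int((t[-1] - t[0]) / base_cfg.drive.period)
        mask = t >= t[-1] - n_per * base_cfg.drive.period
        tw, Fw = t[mask], F[mask]
        manual = float(np.sum(0.5 * (Fw[1:] + Fw[:-1]) * np.diff(tw))
                       / (tw[-1] - tw[0]))
        assert Fmean == pytest.approx(manual, rel=1e-6)
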