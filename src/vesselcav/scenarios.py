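"""Scenario drivers: run one scenario, parameter sweeps, dual-vs-single
comparison, fixture configs and structured outputs.

A *run* executes the full model chain — bubble integration, wall-line
stress fields, wall response, permeability — and reduces it to summary
metrics over the trailing steady-state window:

* per-bubble peak-to-peak radial amplitude;
* time-max |tau_ex| and |sigma_n| over the whole wall line, and at the
  midplane observation point (r = RV, z = 0);
* permeability pulse count and time-integrated excess permeability at the
  observation point;
* for bubble pairs, the mean secondary Bjerknes force.

The midplane point sits symmetrically between the bubbles; note that for
a perfectly symmetric in-phase pair the shear stress vanishes there by
antisymmetry, which is why shear metrics are also reported as wall-line
maxima. Everything is deterministic: identical configs give identical
outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import bubble_dynamics as bd
from . import permeability as perm
from .config import ScenarioConfig, default_scenario
from .wall_mechanics import WallSeries, compute_wall_series

__all__ = [
    "SweepSpec", "RunResult", "run", "run_sweep",
    "compare_single_dual", "write_fixture_configs", "default_scenario",
]

log = logging.getLogger("vesselcav")

#: Sweep axes and their human units (as used in config files and the CLI).
SWEEP_AXES = {"Pd": "kPa", "f": "MHz", "R10": "um", "d": "um"}


@dataclass(frozen=True)
class SweepSpec:
    """One-axis parameter sweep around a base scenario.

    ``values`` are in the axis' human units: Pd in kPa, f in MHz, R10 and
    d in um.
    """

    axis: str
    values: Sequence[float]
    base: ScenarioConfig = field(default_factory=default_scenario)

    def __post_init__(self) -> None:
        if self.axis not in SWEEP_AXES:
            raise ValueError(f"unknown sweep axis {self.axis!r}; "
                             f"choose from {sorted(SWEEP_AXES)}")
        if len(self.values) == 0:
            raise ValueError("sweep needs at least one value")

    def member(self, value: float) -> ScenarioConfig:
        """The scenario for one sweep value."""
        cfg = self.base
        if self.axis == "Pd":
            return cfg.replace(drive=_rep(cfg.drive, Pd=value * 1e3))
        if self.axis == "f":
            return cfg.replace(drive=_rep(cfg.drive, f=value * 1e6))
        if self.axis == "R10":
            return cfg.replace(bubbles=_rep(cfg.bubbles, R10=value * 1e-6))
        return cfg.replace(bubbles=_rep(cfg.bubbles, d=value * 1e-6))


def _rep(obj, **kw):
    import dataclasses

    return dataclasses.replace(obj, **kw)


@dataclass
class RunResult:
    """Bundle of everything one scenario run produced."""

    cfg: ScenarioConfig
    trajectory: bd.Trajectory
    wall: WallSeries
    permeability: perm.PermeabilitySeries
    metrics: dict
    metadata: dict

    def write(self, outdir) -> None:
        """Write trajectory/wall/permeability CSVs and a JSON summary."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        b = self.cfg.bubbles
        self.trajectory.to_frame(
            d=b.d if b.n_bubbles == 2 else None,
            rho_f=self.cfg.gas_liquid.rho_f,
        ).to_csv(outdir / "trajectory.csv", index=False)
        self.wall.to_frame().to_csv(outdir / "wall.csv", index=False)
        self.permeability.to_frame().to_csv(
            outdir / "permeability.csv", index=False)
        summary = {"metrics": self.metrics, "metadata": self.metadata,
                   "config_echo": self.cfg.to_dict()}
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, default=float) + "\n")


def run(cfg: ScenarioConfig, outdir=None) -> RunResult:
    """Execute the full chain for one scenario and reduce to metrics."""
    log.info("simulating %d-bubble scenario (Pd=%.0f kPa, f=%.2f MHz)",
             cfg.bubbles.n_bubbles, cfg.drive.Pd / 1e3, cfg.drive.f / 1e6)
    traj = bd.simulate(cfg)
    wall = compute_wall_series(traj, cfg.vessel, cfg.rheology,
                               cfg.gas_liquid.rho_f)
    ep = cfg.endothelium
    tau = perm.effective_stress(wall.tau_ex, wall.eps, ep.E)
    SI = perm.shape_index(tau, clamp=ep.clamp_negative_tau)
    K = perm.permeability_K(SI, ep)
    pseries = perm.PermeabilitySeries(z=wall.z, t=wall.t, tau=tau, SI=SI, K=K)

    metrics = _metrics(cfg, traj, wall, pseries)
    pseries.metrics = metrics
    metadata = dict(traj.meta)
    metadata.update(wall.meta)
    metadata["n_bubbles"] = cfg.bubbles.n_bubbles
    result = RunResult(cfg, traj, wall, pseries, metrics, metadata)
    if outdir is not None:
        result.write(outdir)
    return result


def _metrics(cfg: ScenarioConfig, traj: bd.Trajectory, wall: WallSeries,
             pseries: perm.PermeabilitySeries) -> dict:
    period = cfg.drive.period
    win = perm.steady_window(traj.t, period, cfg.integration.steady_cycles)
    iz0, _ = wall.at_z(0.0)
    # wall point nearest a bubble (for near-field stress comparisons)
    iznear = int(np.argmin(np.abs(wall.z - traj.positions[0])))

    amp = [float(np.ptp(traj.R[i, win])) for i in range(traj.n_bubbles)]
    m: dict = {
        "amplitude_pp_m": amp,
        "max_abs_tau_wall_Pa": float(np.abs(wall.tau_ex[:, win]).max()),
        "max_abs_sigma_wall_Pa": float(np.abs(wall.sigma_n[:, win]).max()),
        "max_abs_tau_obs_Pa": float(np.abs(wall.tau_ex[iz0, win]).max()),
        "max_abs_sigma_obs_Pa": float(np.abs(wall.sigma_n[iz0, win]).max()),
        "max_abs_sigma_near_Pa": float(np.abs(wall.sigma_n[iznear, win]).max()),
        "max_abs_tau_near_Pa": float(np.abs(wall.tau_ex[iznear, win]).max()),
        "min_sigma_obs_Pa": float(wall.sigma_n[iz0, win].min()),
        "max_sigma_obs_Pa": float(wall.sigma_n[iz0, win].max()),
        "max_abs_w_obs_m": float(np.abs(wall.w_d[iz0, win]).max()),
        "collapsed": traj.collapsed,
    }
    Kobs = pseries.K[iz0]
    _, integral = perm.excess_permeability(
        Kobs, traj.t, period, cfg.endothelium,
        n_periods=cfg.integration.steady_cycles)
    m["integrated_excess_K_s"] = integral
    m["pulse_count_per_s"] = perm.pulse_count(
        Kobs[win], traj.t[win], ep=cfg.endothelium)
    if traj.n_bubbles == 2:
        _, fmean = bd.secondary_bjerknes(
            traj, cfg.bubbles.d, cfg.gas_liquid.rho_f, period=period)
        m["mean_secondary_bjerknes_N"] = fmean
    return m


def run_sweep(spec: SweepSpec, outdir=None) -> pd.DataFrame:
    """Run every member of a sweep; one tidy row per axis value.

    A failed member run is recorded with ``failed=True`` and NaN metrics;
    the sweep continues.
    """
    unit = SWEEP_AXES[spec.axis]
    rows = []
    for v in sorted(spec.values):
        row = {f"{spec.axis}_{unit}": v, "failed": False}
        try:
            res = run(spec.member(v))
            mm = res.metrics
            row.update({
                "amplitude_pp_m": max(mm["amplitude_pp_m"]),
                "max_abs_tau_wall_Pa": mm["max_abs_tau_wall_Pa"],
                "max_abs_sigma_wall_Pa": mm["max_abs_sigma_wall_Pa"],
                "max_abs_sigma_obs_Pa": mm["max_abs_sigma_obs_Pa"],
                "pulse_count_per_s": mm["pulse_count_per_s"],
                "integrated_excess_K_s": mm["integrated_excess_K_s"],
            })
        except Exception as exc:  # keep sweeping past a bad member
            log.error("sweep member %s=%s failed: %s", spec.axis, v, exc)
            row["failed"] = True
            row["error"] = str(exc)
        rows.append(row)
    table = pd.DataFrame(rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / f"sweep_{spec.axis}.csv", index=False)
    return table


def compare_single_dual(base: ScenarioConfig, outdir=None):
    """Dual scenario vs its single-bubble reduction under identical drive.

    Returns ``(summary, dual_result, single_result)`` where ``summary``
    holds the per-bubble amplitude, wall-stress, pulse-count and
    integrated-excess-permeability ratios (dual / single).
    """
    if not base.is_dual:
        raise ValueError("compare_single_dual needs a dual-bubble base config")
    dual = run(base, outdir=Path(outdir) / "dual" if outdir else None)
    single = run(base.single_bubble(),
                 outdir=Path(outdir) / "single" if outdir else None)
    md, ms = dual.metrics, single.metrics
    summary = {
        "amplitude_ratio": max(md["amplitude_pp_m"]) / max(ms["amplitude_pp_m"]),
        "tau_wall_ratio": md["max_abs_tau_wall_Pa"] / ms["max_abs_tau_wall_Pa"],
        "sigma_wall_ratio": (md["max_abs_sigma_wall_Pa"]
                             / ms["max_abs_sigma_wall_Pa"]),
        "sigma_obs_ratio": (md["max_abs_sigma_obs_Pa"]
                            / ms["max_abs_sigma_obs_Pa"]),
        "pulse_count_ratio": (md["pulse_count_per_s"] / ms["pulse_count_per_s"]
                              if ms["pulse_count_per_s"] else float("nan")),
        "enhancement_ratio": perm.enhancement_ratio(
            md["integrated_excess_K_s"], ms["integrated_excess_K_s"]),
        "dual_metrics": md,
        "single_metrics": ms,
    }
    if outdir is not None:
        (Path(outdir) / "comparison.json").write_text(
            json.dumps(summary, indent=2, default=float) + "\n")
    return summary, dual, single


def write_fixture_configs(outdir) -> list:
    """Write the default scenario and the standard sweep configs.

    Emits the reference dual-bubble scenario plus one sweep spec per
    studied axis: Pd in {50, 100, 150} kPa, f in {0.25, 0.5, 0.75, 1.0}
    MHz, R10 in {1, 2, 3, 4} um, d in {10, 16, 26, 36} um (the d grid
    fills in the two smaller spacings around the studied 26/36 um pair).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    base = default_scenario()
    p = outdir / "default.yaml"
    base.save(p)
    paths.append(p)
    grids = {"Pd": [50.0, 100.0, 150.0],
             "f": [0.25, 0.5, 0.75, 1.0],
             "R10": [1.0, 2.0, 3.0, 4.0],
             "d": [10.0, 16.0, 26.0, 36.0]}
    for axis, values in grids.items():
        spec = {"axis": axis, "unit": SWEEP_AXES[axis], "values": values,
                "base": base.to_dict()}
        p = outdir / f"sweep_{axis}.yaml"
        import yaml

        p.write_text(yaml.safe_dump(spec, sort_keys=False))
        paths.append(p)
    return paths
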