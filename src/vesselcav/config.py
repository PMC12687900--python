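"""Scenario configuration: aggregation, defaults, and (de)serialization.

A :class:`ScenarioConfig` fully specifies one simulation — bubbles, vessel,
acoustic drive, gas/liquid constants, rheology mode, endothelium constants
and integration controls. Configs round-trip through YAML or JSON using
human-scale units (um, kPa, MHz) with unit-suffixed keys; all internal
computation is strict SI.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .bubble_dynamics import AcousticDrive, BubbleConfig, GasLiquidParams
from .permeability import EndotheliumParams
from .rheology import BLOOD_DEFAULT, CarreauYasudaParams, ViscosityMode
from .wall_mechanics import VesselConfig

__all__ = ["IntegrationControls", "ScenarioConfig", "default_scenario"]


@dataclass(frozen=True)
class IntegrationControls:
    """Integrator and windowing controls.

    t_end_cycles: run length in acoustic periods; samples_per_cycle:
    uniform output sampling density; steady_cycles: trailing window used
    for all summary metrics (discards the startup transient); r_min_frac:
    collapse guard as a fraction of the rest radius.
    """

    t_end_cycles: float = 30.0
    samples_per_cycle: int = 200
    rtol: float = 1.0e-8
    atol_R: float = 1.0e-14
    atol_Rdot: float = 1.0e-8
    steady_cycles: int = 10
    r_min_frac: float = 0.02

    def __post_init__(self) -> None:
        if self.t_end_cycles <= 0 or self.samples_per_cycle < 8:
            raise ValueError("bad run length or sampling density")
        if not 0.0 < self.r_min_frac < 1.0:
            raise ValueError("collapse guard must lie in (0, 1)")


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything needed to run one scenario."""

    bubbles: BubbleConfig = field(default_factory=BubbleConfig)
    drive: AcousticDrive = field(default_factory=AcousticDrive)
    gas_liquid: GasLiquidParams = field(default_factory=GasLiquidParams)
    rheology: ViscosityMode = field(default_factory=ViscosityMode)
    vessel: VesselConfig = field(default_factory=VesselConfig)
    endothelium: EndotheliumParams = field(default_factory=EndotheliumParams)
    integration: IntegrationControls = field(default_factory=IntegrationControls)

    @property
    def is_dual(self) -> bool:
        return self.bubbles.n_bubbles == 2

    def single_bubble(self) -> "ScenarioConfig":
        """The single-bubble reduction: drop bubble 2, keep everything else."""
        bub = dataclasses.replace(self.bubbles, R20=None)
        return dataclasses.replace(self, bubbles=bub)

    def replace(self, **kwargs) -> "ScenarioConfig":
        return dataclasses.replace(self, **kwargs)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        b, dr, g, rh = self.bubbles, self.drive, self.gas_liquid, self.rheology
        v, ep, it = self.vessel, self.endothelium, self.integration
        d: dict = {
            "bubbles": {"R10_um": b.R10 * 1e6, "d_um": b.d * 1e6},
            "drive": {"Pd_kPa": dr.Pd / 1e3, "f_MHz": dr.f / 1e6,
                      "phase_rad": dr.phase},
            "gas": {"kappa": g.kappa, "pv_Pa": g.pv,
                    "sigma_N_per_m": g.sigma_g},
            "liquid": {"p0_Pa": g.p0, "rho_kg_m3": g.rho_f},
            "rheology": {"kind": rh.kind, "constant_Pa_s": rh.constant_value,
                         "carreau_yasuda": {
                             "eta0_Pa_s": rh.params.eta0,
                             "eta_inf_Pa_s": rh.params.eta_inf,
                             "lambda_s": rh.params.lam,
                             "n": rh.params.n, "a": rh.params.a}},
            "vessel": {"RV_um": v.RV * 1e6, "L_um": v.L * 1e6,
                       "rho_kg_m3": v.rho_s, "E_Pa": v.E, "nu": v.nu,
                       "h_um": v.h * 1e6, "zeta": v.zeta,
                       "plane_strain": v.plane_strain, "n_axial": v.n_axial},
            "endothelium": {"Rcell_um": ep.Rcell * 1e6,
                            "w_half_nm": ep.w_half * 1e9, "E_Pa": ep.E,
                            "clamp_negative_tau": ep.clamp_negative_tau,
                            "prefactor": ep.prefactor},
            "integration": {"t_end_cycles": it.t_end_cycles,
                            "samples_per_cycle": it.samples_per_cycle,
                            "rtol": it.rtol, "atol_R": it.atol_R,
                            "atol_Rdot": it.atol_Rdot,
                            "steady_cycles": it.steady_cycles,
                            "r_min_frac": it.r_min_frac},
        }
        if b.R20 is not None:
            d["bubbles"]["R20_um"] = b.R20 * 1e6
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        base = cls()
        bd = d.get("bubbles", {})
        bubbles = BubbleConfig(
            R10=bd.get("R10_um", base.bubbles.R10 * 1e6) / 1e6,
            R20=(bd["R20_um"] / 1e6) if bd.get("R20_um") is not None else None,
            d=bd.get("d_um", base.bubbles.d * 1e6) / 1e6,
        )
        dd = d.get("drive", {})
        drive = AcousticDrive(Pd=dd.get("Pd_kPa", base.drive.Pd / 1e3) * 1e3,
                              f=dd.get("f_MHz", base.drive.f / 1e6) * 1e6,
                              phase=dd.get("phase_rad", 0.0))
        gd, ld = d.get("gas", {}), d.get("liquid", {})
        g0 = base.gas_liquid
        glp = GasLiquidParams(kappa=gd.get("kappa", g0.kappa),
                              pv=gd.get("pv_Pa", g0.pv),
                              sigma_g=gd.get("sigma_N_per_m", g0.sigma_g),
                              p0=ld.get("p0_Pa", g0.p0),
                              rho_f=ld.get("rho_kg_m3", g0.rho_f))
        rd = d.get("rheology", {})
        cyd = rd.get("carreau_yasuda")
        cy = (CarreauYasudaParams(eta0=cyd["eta0_Pa_s"],
                                  eta_inf=cyd["eta_inf_Pa_s"],
                                  lam=cyd["lambda_s"], n=cyd["n"], a=cyd["a"])
              if cyd else BLOOD_DEFAULT)
        mode = ViscosityMode(kind=rd.get("kind", "carreau_yasuda"),
                             constant_value=rd.get("constant_Pa_s", 0.0035),
                             params=cy)
        vd = d.get("vessel", {})
        v0 = base.vessel
        vessel = VesselConfig(RV=vd.get("RV_um", v0.RV * 1e6) / 1e6,
                              L=vd.get("L_um", v0.L * 1e6) / 1e6,
                              rho_s=vd.get("rho_kg_m3", v0.rho_s),
                              E=vd.get("E_Pa", v0.E), nu=vd.get("nu", v0.nu),
                              h=vd.get("h_um", v0.h * 1e6) / 1e6,
                              zeta=vd.get("zeta", v0.zeta),
                              plane_strain=vd.get("plane_strain", False),
                              n_axial=vd.get("n_axial", v0.n_axial))
        ed = d.get("endothelium", {})
        e0 = base.endothelium
        endo = EndotheliumParams(
            Rcell=ed.get("Rcell_um", e0.Rcell * 1e6) / 1e6,
            w_half=ed.get("w_half_nm", e0.w_half * 1e9) / 1e9,
            E=ed.get("E_Pa", e0.E),
            clamp_negative_tau=ed.get("clamp_negative_tau", True),
            prefactor=ed.get("prefactor"))
        it = d.get("integration", {})
        i0 = base.integration
        ictl = IntegrationControls(
            t_end_cycles=it.get("t_end_cycles", i0.t_end_cycles),
            samples_per_cycle=it.get("samples_per_cycle", i0.samples_per_cycle),
            rtol=it.get("rtol", i0.rtol),
            atol_R=it.get("atol_R", i0.atol_R),
            atol_Rdot=it.get("atol_Rdot", i0.atol_Rdot),
            steady_cycles=it.get("steady_cycles", i0.steady_cycles),
            r_min_frac=it.get("r_min_frac", i0.r_min_frac))
        return cls(bubbles=bubbles, drive=drive, gas_liquid=glp, rheology=mode,
                   vessel=vessel, endothelium=endo, integration=ictl)

    def save(self, path) -> None:
        path = Path(path)
        d = self.to_dict()
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(d, indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def load(cls, path) -> "ScenarioConfig":
        """Load a YAML or JSON scenario file (auto-detected)."""
        text = Path(path).read_text()
        try:
            d = json.loads(text)
        except json.JSONDecodeError:
            d = yaml.safe_load(text)
        if not isinstance(d, dict):
            raise ValueError(f"not a scenario config: {path}")
        return cls.from_dict(d)


def default_scenario() -> ScenarioConfig:
    """The reference dual-bubble scenario.

    Two 2 um bubbles 10 um apart on the axis of a 5 um radius, 40 um long
    vessel, driven at 30 kPa / 1.5 MHz, with the shear-thinning blood
    rheology and 30-cycle integration (metrics over the last 10 cycles).
    """
    return ScenarioConfig(bubbles=BubbleConfig(R10=2e-6, R20=2e-6, d=10e-6))
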