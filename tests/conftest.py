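import numpy as np
import pytest

import vesselcav as vc


@pytest.fixture(scope="session")
def base_cfg() -> vc.ScenarioConfig:
    """Reference dual-bubble scenario (2 um pair, d = 10 um, 30 kPa, 1.5 MHz)."""
    return vc.default_scenario()


@pytest.fixture(scope="session")
def dual_run(base_cfg):
    return vc.run(base_cfg)


@pytest.fixture(scope="session")
def single_run(base_cfg):
    return vc.run(base_cfg.single_bubble())


@pytest.fixture(scope="session")
def single_const_run(base_cfg):
    cfg = base_cfg.single_bubble().replace(
        rheology=vc.ViscosityMode(kind="constant", constant_value=0.0035))
    return vc.run(cfg)


def steady_mask(cfg: vc.ScenarioConfig, t: np.ndarray) -> np.ndarray:
    """Mask for the trailing steady-state metric window of a run."""
    n = cfg.integration.steady_cycles
    return t >= t[-1] - n * cfg.drive.period
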