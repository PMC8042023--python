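import numpy as np
import pandas as pd
import pytest

from wallmark import kinematics, simulate
from wallmark.config import RenderConfig, preset


@pytest.fixture
def lb_config():
    """LB-medium preset: inert cap 0.27 um, 10-min frames over 60 min."""
    return preset("LB", n_motors=30, rng_seed=42)


@pytest.fixture
def lb_cell(lb_config):
    return simulate.simulate_elongation(lb_config)


@pytest.fixture
def triggered_cell():
    """A cell elongated until the division trigger length."""
    cfg = preset("LB", n_motors=40, rng_seed=7)
    return simulate.simulate_elongation(cfg, until_trigger=True)


@pytest.fixture
def rendered_movie():
    cfg = preset("LB", n_motors=6, rng_seed=11, render=RenderConfig(shot_noise=True))
    cell = simulate.simulate_elongation(cfg)
    return cell, simulate.render_frames(cell)


def velocity_table(positions: pd.DataFrame) -> pd.DataFrame:
    """Per-motor V_Py fits from a position table."""
    traces = kinematics.traces_from_table(positions)
    return pd.DataFrame([kinematics.fit_VPy(t).__dict__ for t in traces])
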