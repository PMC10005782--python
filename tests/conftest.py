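import numpy as np
import pytest

from mtkymo import model


@pytest.fixture(scope="session")
def baseline_condition():
    """Small baseline condition reused by several test modules."""
    return model.simulate_condition(model.BASELINE_PARAMS, 30, 1200.0, master_seed=101)


def make_three_phase_trace(dt=3.0, v_g=1.0, t_grow=60.0, t_pause=30.0, v_s=10.0,
                           noise_sd=0.0, rng=None):
    """Piecewise-linear tip trace: growth, pause, shrink back to zero."""
    from mtkymo.kymo import Trace

    peak = v_g * t_grow / 60.0
    t_shrink = peak / v_s * 60.0
    total = t_grow + t_pause + t_shrink
    times = np.arange(0.0, total + dt / 2, dt)
    pos = np.where(
        times <= t_grow, v_g * times / 60.0,
        np.where(times <= t_grow + t_pause, peak,
                 peak - v_s * (times - t_grow - t_pause) / 60.0),
    )
    pos = np.clip(pos, 0.0, None)
    if noise_sd > 0:
        rng = rng or np.random.default_rng(0)
        pos = np.clip(pos + rng.normal(0, noise_sd, pos.size), 0.0, None)
    return Trace(frame_times=times, positions=pos, calibration=model.Calibration(frame_interval=dt))
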