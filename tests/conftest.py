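import numpy as np
import pytest

from tumortrack.motion import (
    IRMarkerTrace,
    TargetTrace,
    TrackingLogfile,
    split_logfile,
)
from tumortrack.simulate import DirectionalCoupling, SimulatorConfig, simulate_logfile

IR_DT = 1.0 / 60.0


def grid(duration: float) -> np.ndarray:
    return np.arange(int(round(duration * 60))) / 60.0


def make_logfile(
    duration: float = 30.0,
    det_gap: float = 0.2,
    marker_fn=None,
    target_fn=None,
    n_markers: int = 4,
    session_id: str = "fixture",
) -> TrackingLogfile:
    """Deterministic analytic logfile: every marker follows ``marker_fn(t)``
    (default: 5 mm sine, 4 s period), the target ``target_fn(t) -> (3,)``
    (default: per-axis scaled copies of the marker signal)."""
    t = grid(duration)
    if marker_fn is None:
        marker_fn = lambda tt: 5.0 * np.sin(2 * np.pi * tt / 4.0)
    if target_fn is None:
        target_fn = lambda tt: np.stack(
            [0.3 * marker_fn(tt), 2.0 * marker_fn(tt), 0.4 * marker_fn(tt)], axis=-1
        )
    markers = [
        IRMarkerTrace(i + 1, t, np.asarray(marker_fn(t), dtype=float))
        for i in range(n_markers)
    ]
    det_t = np.arange(det_gap, duration - IR_DT, det_gap)
    target = TargetTrace(det_t, np.atleast_2d(target_fn(det_t)))
    return TrackingLogfile(session_id=session_id, markers=markers, target=target)


@pytest.fixture(scope="session")
def sine_logfile():
    return make_logfile()


@pytest.fixture(scope="session")
def sim_logfile():
    return simulate_logfile(SimulatorConfig(), seed=42)


@pytest.fixture(scope="session")
def sim_split(sim_logfile):
    return split_logfile(sim_logfile, 0.75)


@pytest.fixture(scope="session")
def noiseless_linear_config():
    """Linear, instantaneous, noiseless coupling: the regression baseline's
    own model class."""
    return SimulatorConfig(
        noise_sd_marker=0.0,
        noise_sd_target=0.0,
        marker_gain_range=(1.0, 1.0),
        target_coupling={
            "rl": DirectionalCoupling(gain=0.3, lag=0.0),
            "si": DirectionalCoupling(gain=2.0, lag=0.0),
            "ap": DirectionalCoupling(gain=0.4, lag=0.0),
        },
    )
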