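import numpy as np
import pytest

from dxtrack import AngularTrajectory, DetectorGeometry


def make_traj(chi, theta=None, dt=0.1, tid="t0", **kw):
    """Build a trajectory from angle arrays with a uniform time grid."""
    chi = np.asarray(chi, dtype=float)
    if theta is None:
        theta = np.zeros_like(chi)
    t = dt * np.arange(len(chi))
    return AngularTrajectory(id=tid, t=t, chi=chi, theta=np.asarray(theta, float), **kw)


def linear_traj(v_chi, n=11, dt=0.1, chi0=0.0, tid="lin"):
    t = dt * np.arange(n)
    return make_traj(chi0 + v_chi * t, dt=dt, tid=tid)


def brownian_ensemble(n_traj, n_frames, d=1.0, drift=0.0, dt=0.1, seed=0):
    """Reference generator used as an independent check on the simulator."""
    rng = np.random.default_rng(seed)
    steps = rng.normal(drift * dt, np.sqrt(2 * d * dt),
                       size=(n_traj, n_frames - 1))
    pos = np.concatenate(
        [np.zeros((n_traj, 1)), np.cumsum(steps, axis=1)], axis=1
    )
    return [make_traj(pos[i], dt=dt, tid=f"b{i}") for i in range(n_traj)]


@pytest.fixture
def geom():
    return DetectorGeometry(
        beam_center_x=200.0, beam_center_y=200.0, camera_length=100.0
    )
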