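import numpy as np
import pytest

from pathmetad import (
    LangevinParams,
    ReferencePath,
    make_double_well,
    make_host_guest,
)


@pytest.fixture(scope="session")
def host_guest():
    """Two-channel bead system: channel 1 saddle at 6, channel 2 at 10
    kcal/mol above bulk, cavity 8 kcal/mol deep."""
    return make_host_guest(6.0, 10.0, 8.0)


@pytest.fixture(scope="session")
def double_well_asym():
    return make_double_well(5.0, 4.0, 2.0)


@pytest.fixture()
def langevin_params():
    return LangevinParams(dt=0.005, friction=1.0, temperature=300.0, seed=7)


def straight_line_frames(n_frames=40, step=0.5, n_host=4):
    """Synthetic trajectory frames: a static 4-point host plus one guest
    moving along +x at constant speed; guest is atom index n_host."""
    host = np.array([[0.0, 3.0, 0.0], [0.0, -3.0, 0.0],
                     [-3.0, 0.0, 0.0], [-1.0, 0.0, 2.0]])[:n_host]
    frames = []
    for i in range(n_frames):
        f = np.zeros((n_host + 1, 3))
        f[:n_host] = host
        f[n_host] = [i * step, 0.0, 0.0]
        frames.append(f)
    return frames


@pytest.fixture()
def line_path():
    """Reference path of 12 frames along a straight guest track, 1 A apart."""
    frames = straight_line_frames(n_frames=12, step=1.0)
    return ReferencePath(
        frames=frames,
        align_selection=np.arange(4),
        distance_selection=np.array([4]),
        lambda_=np.log(2.0),          # ln2 / (1 A)^2 spacing
        spacing_target=1.0,
    )
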