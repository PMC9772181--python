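import numpy as np
import pytest

from tiltscope.stimulus import StageTrajectory


@pytest.fixture
def static_traj():
    """A 3 s motionless trajectory at 1 kHz (30 camera frames at 10 /s)."""
    n = 3001
    t = np.arange(n) / 1000.0
    z = np.zeros(n)
    return StageTrajectory(t=t, theta=z, omega=z, alpha=z,
                           protocol="static", sample_rate=1000.0)


def small_acq(fov=128):
    from tiltscope.synthetic import Acquisition

    return Acquisition(fov=(fov, fov))


@pytest.fixture
def clean_bead_stack(static_traj):
    """Artifact-free, noise-free static bead stack plus its field."""
    from tiltscope.synthetic import (ArtifactModel, bead_sources,
                                     make_bead_field, render_stack)

    acq = small_acq()
    beads = make_bead_field(15, fov=acq.fov, seed=5)
    stack = render_stack(bead_sources(beads), static_traj,
                         artifact=ArtifactModel.disabled(), acq=acq, seed=5)
    return stack, beads, acq
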