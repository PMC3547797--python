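import numpy as np
import pytest

from refix.core import Trajectory
from refix.synthetic import CohortSpec, generate_cohort


def make_trajectory(points, durations=None, subject="s0", image="im0",
                    trial="t0"):
    pts = np.asarray(points, dtype=float)
    if durations is None:
        durations = np.full(len(pts), 200.0)
    return Trajectory(subject, image, trial, pts[:, 0], pts[:, 1],
                      np.asarray(durations, dtype=float))


@pytest.fixture(scope="session")
def small_cohort():
    """A small but statistically meaningful cohort, shared across tests."""
    spec = CohortSpec(n_subjects=6, n_images=6, trials_per_image=3)
    return generate_cohort(spec, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
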