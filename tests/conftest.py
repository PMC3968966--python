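import numpy as np
import pytest

from trajclust.schema import DatasetSchema, Trajectory


@pytest.fixture
def binary_schema():
    """One binary observation channel, no covariates."""
    return DatasetSchema(observation_channels=(("obs", ("A", "B")),))


@pytest.fixture
def two_channel_schema():
    """Two observation channels (binary + ternary) with one binary covariate."""
    return DatasetSchema(
        observation_channels=(("u", ("x", "y")), ("v", ("x", "y", "z"))),
        covariate_channels=(("c", ("lo", "hi")),),
    )


@pytest.fixture
def toy_line_distance():
    """Pairwise distances of the points {0, 1, 10, 11} on a line."""
    pts = np.array([0.0, 1.0, 10.0, 11.0])
    return np.abs(pts[:, None] - pts[None, :])


def make_trajectory(obs, cov=None, subject_id="s"):
    obs = np.atleast_2d(np.asarray(obs))
    if obs.shape[0] == 1 and obs.shape[1] > 1 and obs.ndim == 2:
        obs = obs.T if obs.shape[0] == 1 else obs
    return Trajectory(subject_id=subject_id, observations=obs, covariates=cov)
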