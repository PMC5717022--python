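import numpy as np
import pytest

from gfstrack.config import RunConfig
from gfstrack.synthetic import GroupConfig, StimulusEvent, StimulusScript, default_script


@pytest.fixture(scope="session")
def script() -> StimulusScript:
    return default_script()


@pytest.fixture(scope="session")
def group_config() -> GroupConfig:
    return GroupConfig(seed=7)


@pytest.fixture(scope="session")
def run_config() -> RunConfig:
    return RunConfig(seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_series(values, dt=1.0, t0=0.0, name="x", subject="s"):
    """Uniform FeatureSeries from a value list (test helper)."""
    from gfstrack.core_io import FeatureSeries

    v = np.asarray(values, dtype=float)
    return FeatureSeries(
        name=name, units="", times=t0 + np.arange(len(v)) * dt, values=v,
        subject_id=subject,
    )
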