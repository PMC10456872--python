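import numpy as np
import pytest

from barogeo.simulate import SimConfig, simulate_subject_series
from barogeo.pipeline import series_to_features


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230810)


@pytest.fixture(scope="session")
def subject_series():
    """One default (control-like) subject's event series + ground truth."""
    cfg = SimConfig(seed=1)
    return simulate_subject_series(cfg, "CON", seed=42, subject_id="CON-00")


@pytest.fixture(scope="session")
def subject_features(subject_series):
    series, _ = subject_series
    return series_to_features(series)
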