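import numpy as np
import pytest

from somnipose import pipeline
from somnipose.io_streams import SensorStream
from somnipose.simulate import default_config, simulate_session


def make_stream(acc, timestamps=None, site="chest", rate=60.0):
    """Small helper: build a stream from a list of (ax, ay, az) triples."""
    acc = np.asarray(acc, dtype=float).reshape(-1, 3)
    if timestamps is None:
        timestamps = np.arange(acc.shape[0]) * 100
    return SensorStream(site=site, timestamps_ms=np.asarray(timestamps),
                        acc=acc, nominal_rate_hz=rate)


@pytest.fixture(scope="session")
def separable_session():
    return simulate_session(default_config("separable", seed=11))


@pytest.fixture(scope="session")
def separable_dataset(separable_session):
    dataset, _ = pipeline.build_training_dataset(
        separable_session.chest, separable_session.wrist
    )
    return dataset
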