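import numpy as np
import pytest

from actiseg.io import IntervalAnnotation, SensorSequence
from actiseg.simulate import simulate_np_cms, simulate_wp_cms


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_seq(rng):
    return SensorSequence(rng.standard_normal((6, 40)))


@pytest.fixture(scope="session")
def np_records():
    """Small annotated non-periodic dataset shared across tests."""
    return simulate_np_cms(24, rng_seed=7)


@pytest.fixture(scope="session")
def trained_detector(np_records):
    from actiseg.detector import IntervalDetector
    return IntervalDetector(epochs=15, random_state=0).fit(np_records[:20])


@pytest.fixture(scope="session")
def trained_recognizer(np_records, trained_detector):
    # joint training refines the shared encoder in place; train on a copy
    # so `trained_detector` stays a stage-1 model for the other tests
    import copy
    from actiseg.recognizer import IntervalRecognizer
    rec = IntervalRecognizer(epochs=8, random_state=0)
    rec.fit(np_records[:20], detector=copy.deepcopy(trained_detector))
    return rec


@pytest.fixture(scope="session")
def wp_records():
    return simulate_wp_cms(6, n_cycles_per_stroke=5, rng_seed=11)


def random_interval(rng, lo=0, hi=400, min_len=2, max_len=120):
    start = int(rng.integers(lo, hi - min_len))
    length = int(rng.integers(min_len, min(max_len, hi - start) + 1))
    return IntervalAnnotation(start, start + length)
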