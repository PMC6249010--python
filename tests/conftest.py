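import numpy as np
import pytest

from fishact import ActivitySample, ActivityTrace


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_trace(values, dt=1.0, t0=1.0, animal_id="a1", condition="ctrl"):
    """Build an ActivityTrace from a bare improved-activity series.

    pixel_count/avg_distance are filled with a consistent factorization
    (count 1 would force activity 0, so count is 2 and distance = value/2).
    """
    samples = [
        ActivitySample(
            time=t0 + i * dt,
            pixel_count=2 if v > 0 else 0,
            avg_distance=v / 2.0 if v > 0 else 0.0,
            improved_activity=float(v),
        )
        for i, v in enumerate(values)
    ]
    return ActivityTrace(samples=samples, animal_id=animal_id, condition=condition)
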