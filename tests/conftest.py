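import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_intervals(rows):
    """rows: (tag, box, start_hours, end_hours) relative to a fixed origin."""
    t0 = pd.Timestamp("2019-12-20")
    return pd.DataFrame(
        {
            "tag_id": [r[0] for r in rows],
            "box_id": [r[1] for r in rows],
            "t_start": [t0 + pd.Timedelta(hours=r[2]) for r in rows],
            "t_end": [t0 + pd.Timedelta(hours=r[3]) for r in rows],
            "quality": "paired",
        }
    )


@pytest.fixture
def interval_factory():
    return make_intervals


def random_instance(rng, n_intervals, n_animals, n_boxes, span_hours=24.0):
    starts = rng.uniform(0, span_hours, n_intervals)
    lengths = rng.exponential(1.0, n_intervals)
    return make_intervals(
        [
            (
                f"A{rng.integers(n_animals):02d}",
                f"B{rng.integers(n_boxes):02d}",
                s,
                min(s + d, span_hours),
            )
            for s, d in zip(starts, lengths)
        ]
    )


@pytest.fixture
def random_instance_factory():
    return random_instance
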