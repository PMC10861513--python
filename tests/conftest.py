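import numpy as np
import pandas as pd
import pytest

from vernalign.expression import ExpressionSeries, TimePointProfile
from vernalign.simulate import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def tiny_config() -> SimulationConfig:
    """Small but fully featured simulation: ~170 genes, all flag types."""
    return SimulationConfig(n_families=50, seed=123)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return generate_dataset(tiny_config)


def make_profile(values: dict[str, list[float]], days: list[int],
                 variety: str = "A", tissue: str = "apex") -> TimePointProfile:
    """Hand-built replicate-collapsed profile from per-gene day vectors."""
    frame = pd.DataFrame.from_dict(values, orient="index", columns=days)
    return TimePointProfile(values=frame, variety=variety, tissue=tissue)


@pytest.fixture
def toy_profile_pair():
    """Two 2-gene profiles with hand-checkable distances:
    row days t1=(0,0), t2=(3,4); col days w1=(0,0), w2=(6,8)."""
    row = make_profile({"g1": [0.0, 3.0], "g2": [0.0, 4.0]}, [1, 2])
    col = make_profile({"g1": [0.0, 6.0], "g2": [0.0, 8.0]}, [1, 2], variety="B")
    return row, col
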