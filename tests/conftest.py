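import numpy as np
import pandas as pd
import pytest

from phasic.containers import CountMatrix, PipelineConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_counts():
    """3 genes x 2 units with known column sums {5, 10}."""
    return CountMatrix(
        ["g1", "g2", "g3"], ["u1", "u2"],
        np.array([[0, 1], [5, 2], [0, 7]]), "umi")


@pytest.fixture
def config():
    return PipelineConfig()


def two_group_annotations(n_per_group, detection=None, seed=0):
    """Balanced G1/G2M annotation table with a detection covariate."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    det = rng.uniform(0.5, 1.0, n) if detection is None else detection
    return pd.DataFrame({
        "unit_id": [f"u{i}" for i in range(n)],
        "phase": ["G1"] * n_per_group + ["G2M"] * n_per_group,
        "detection_fraction": det,
    })
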