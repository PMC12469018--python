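import numpy as np
import pytest

from neurolatent.core_io import CohortDataset, TimeCourse, default_network_map
from neurolatent.model import HierarchicalAttentionNet, ModelConfig


@pytest.fixture(scope="session")
def network_map():
    return default_network_map(53)


@pytest.fixture(scope="session")
def tiny_model_cfg():
    """A deliberately small architecture for fast unit tests."""
    return ModelConfig(C=6, D_enc=8, D_main=5, window_len=4, D_attn=4)


@pytest.fixture()
def tiny_model(tiny_model_cfg):
    return HierarchicalAttentionNet(tiny_model_cfg, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_cohort(n=6, t=12, c=4, seed=0, labels=None, cohort_id="TEST"):
    rng = np.random.default_rng(seed)
    subjects = [
        TimeCourse(rng.standard_normal((t, c)), subject_id=f"S{i:03d}")
        for i in range(n)
    ]
    if labels is None:
        labels = np.tile([0, 1], n)[:n]
    return CohortDataset(subjects, np.asarray(labels), cohort_id)


@pytest.fixture()
def tiny_cohort():
    return make_cohort()
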