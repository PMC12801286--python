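import numpy as np
import pytest

from tlsview.heatmap_core import TissueHeatmap


def make_hm(labels, subtypes=None, pitch=0.064, slide_id="s"):
    labels = np.asarray(labels, dtype=np.int16)
    if subtypes is None:
        subtypes = np.where(labels == 3, 1, 0)
    return TissueHeatmap(labels, np.asarray(subtypes, dtype=np.int16), pitch, slide_id)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_heatmap_factory():
    """Random label grids (with valid subtype channels) for property tests."""

    def factory(seed, shape=(24, 24), p=(0.55, 0.15, 0.2, 0.1)):
        r = np.random.default_rng(seed)
        labels = r.choice([0, 1, 2, 3], size=shape, p=p)
        subtypes = np.where(labels == 3, r.integers(1, 4, size=shape), 0)
        return TissueHeatmap(labels, subtypes, 0.064, f"rand{seed}")

    return factory
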