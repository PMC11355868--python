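import numpy as np
import pytest

from esfpnet.data import SynthSpec, synth_dataset, synth_frame

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def synth_root(tmp_path_factory):
    """Small on-disk synthetic dataset shared across tests (4 cases x 3)."""
    root = tmp_path_factory.mktemp("synthdata")
    synth_dataset(root, n_cases=4, frames_per_case=3, lesion_fraction=0.4, seed=11)
    return root


@pytest.fixture(scope="session")
def lesion_frame_pair():
    """One deterministic synthetic lesion frame + mask at native scale."""
    rng = np.random.default_rng(77)
    return synth_frame(SynthSpec(), rng, lesion=True)
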