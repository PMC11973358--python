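import numpy as np
import pytest

from histonet.arch import ArchConfig
from histonet.synthdata import SyntheticConfig, generate_arrays


def tiny_cfg(variant="htrec", **kw):
    """Small-footprint config for fast structural tests."""
    defaults = dict(
        variant=variant,
        base_width=8,
        input_size=64,
        stage_depths=(1, 1, 1, 1),
        cbam_reduction=8,
    )
    defaults.update(kw)
    return ArchConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_cfg_factory():
    return tiny_cfg


@pytest.fixture(scope="session")
def small_dataset():
    """30 images per class at 64 px; deterministic."""
    return generate_arrays(
        SyntheticConfig(n_per_class=(30, 30, 30), image_size=64, seed=11)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
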