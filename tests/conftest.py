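import numpy as np
import pytest

from medsegsplit.models import build_model
from medsegsplit.synthetic_data import SyntheticTaskSpec, generate_dataset


@pytest.fixture(scope="session")
def multiclass_samples():
    """12 small 64-px nested-structure samples."""
    return generate_dataset(SyntheticTaskSpec("multiclass5", n_samples=12, image_size=64, seed=7))


@pytest.fixture(scope="session")
def binary_samples():
    return generate_dataset(
        SyntheticTaskSpec("binary_lesion", n_samples=8, image_size=64, seed=11)
    )


@pytest.fixture
def tiny_unet():
    """5-class UNet small enough for fast training tests."""
    return build_model("unet", num_classes=5, base_width=4, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
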