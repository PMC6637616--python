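import numpy as np
import pytest

import fundlocate as fl


@pytest.fixture(scope="session")
def small_clean_image():
    """One deterministic clean synthetic fundus image + ground truth."""
    spec = fl.SyntheticSpec(image_size=600, seed=42, noise_sigma=0.0)
    return fl.generate_image(spec)


@pytest.fixture(scope="session")
def small_suite():
    """A 12-image mixed suite at small resolution for fast integration tests."""
    items, manifest = fl.generate_dataset(
        n=12, ranges={"image_size": [500, 640]}, glaucoma_fraction=0.25, seed=7
    )
    return items, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
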