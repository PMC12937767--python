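import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/oracles.py


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_standard_image(rng):
    """A 224x224x3 random image in [0, 255]."""
    return rng.integers(0, 256, size=(224, 224, 3)).astype(float)


@pytest.fixture
def toy_manifest():
    """Five patients, 3 images each, two classes."""
    rows = []
    for p in range(5):
        for i in range(3):
            rows.append(
                dict(
                    image_id=f"img_{p}_{i}",
                    patient_id=f"pat_{p}",
                    label="A" if p < 3 else "B",
                    origin="original",
                    parent_image_id=None,
                )
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small maximally-separable synthetic dataset shared across tests."""
    from hchsnet.synthetic import gen_dataset

    return gen_dataset(8, separability=1.0, seed=7, size=128)
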