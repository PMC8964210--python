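import numpy as np
import pytest

from cytoswarm.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture
def square_cell():
    """Hand-countable cell: 10x10 uniform-gray-100 nucleus, 300-px uniform
    gray-180 cytoplasm."""
    gray = np.zeros((25, 25), dtype=int)
    nucleus = np.zeros((25, 25), dtype=bool)
    nucleus[5:15, 5:15] = True
    cytoplasm = np.zeros((25, 25), dtype=bool)
    cytoplasm[0:5, :] = True  # 125 px
    cytoplasm[15:22, :] = True  # 175 px
    gray[nucleus] = 100
    gray[cytoplasm] = 180
    assert cytoplasm.sum() == 300
    return gray, nucleus, cytoplasm


@pytest.fixture
def textured_disk():
    """Seeded anisotropic texture on a disk mask (for rotation tests)."""
    rng = np.random.default_rng(7)
    yy, xx = np.mgrid[0:64, 0:64]
    gray = 128 + 30 * np.sin(2 * np.pi * xx / 5.0) + rng.normal(0, 5, (64, 64))
    gray = np.clip(np.rint(gray), 0, 255).astype(int)
    mask = (yy - 32) ** 2 + (xx - 32) ** 2 <= 25**2
    return gray, mask


@pytest.fixture(scope="session")
def small_dataset():
    """Six cells per class, default profiles."""
    config = GeneratorConfig(counts_per_class=(6,) * 7, seed=7)
    return generate_dataset(config)


@pytest.fixture
def two_blobs():
    rng = np.random.default_rng(11)
    X = np.vstack([rng.normal(0, 0.5, (200, 2)), rng.normal(5, 0.5, (200, 2))])
    y = np.array(["a"] * 200 + ["b"] * 200)
    return X, y
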