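import numpy as np
import pytest

from seamseg.synthetic import (GeneratorConfig, ImageMaskPair, generate_dataset,
                               render_pair, sample_scene)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_gen_config():
    """A small, quick-to-render scene configuration shared across tests."""
    return GeneratorConfig(canvas=(96, 96), n_cells=(3, 6),
                           semi_major=(6.0, 12.0), blur_sigma=0.8)


@pytest.fixture(scope="session")
def sample_pair(small_gen_config) -> ImageMaskPair:
    return render_pair(sample_scene(small_gen_config, seed=7))


@pytest.fixture(scope="session")
def small_dataset(small_gen_config):
    return generate_dataset(small_gen_config, 8, seed=11)


def checkerboard_pair(h=32, w=32) -> ImageMaskPair:
    """Pair whose image encodes pixel coordinates, for geometric-op oracles."""
    rows, cols = np.mgrid[0:h, 0:w]
    image = np.stack([rows / h, cols / w, (rows + cols) % 2], axis=-1).astype(np.float32)
    mask = ((rows + cols) % 2).astype(np.uint8)
    return ImageMaskPair(image=image, mask=mask, instances=None, meta={})
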