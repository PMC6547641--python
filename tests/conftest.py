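import numpy as np
import pytest

from rnadist.segmentation import BinaryMask
from rnadist.synthetic import SyntheticCellSpec, generate


def make_disk_mask(shape, center, radius, kind="cell"):
    ys, xs = np.mgrid[0 : shape[0], 0 : shape[1]]
    return BinaryMask(
        (xs - center[0]) ** 2 + (ys - center[1]) ** 2 <= radius**2, kind=kind
    )


@pytest.fixture(scope="session")
def disk_cell():
    """256x256 disk cell mask (r=80) with nucleus (r=24) offset by 16 px."""
    cell = make_disk_mask((256, 256), (127.5, 127.5), 80.0)
    nucleus = make_disk_mask((256, 256), (143.5, 127.5), 24.0, kind="nucleus")
    return cell, nucleus


@pytest.fixture(scope="session")
def uniform_synthetic():
    spec = SyntheticCellSpec(
        image_size=(256, 256),
        cell_shape=("disk", 80),
        nucleus_shape=("disk", 24),
        nucleus_offset=(16.0, 0.0),
        seed=11,
    )
    return generate(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
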