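import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cellsoc.synthesis import _add_blob

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def blob_image():
    """30 well-separated Gaussian nuclei on a 512x512 map, with truth centres."""
    rng = np.random.default_rng(5)
    img = np.zeros((512, 512))
    centres = []
    while len(centres) < 30:
        x, y = rng.uniform(30, 482, 2)
        if centres and min((x - a) ** 2 + (y - b) ** 2 for a, b in centres) < 40**2:
            continue
        centres.append((x, y))
    for x, y in centres:
        _add_blob(img, x, y, 5.0, 1.0)
    return img, np.array(centres)


@pytest.fixture(scope="session")
def touching_disks():
    """Two ~300 px disks overlapping by roughly 10% of their area."""
    from skimage.draw import disk

    img = np.zeros((100, 120))
    rr, cc = disk((50, 45), 9.8, shape=img.shape)
    img[rr, cc] = 1.0
    rr, cc = disk((50, 60), 9.8, shape=img.shape)
    img[rr, cc] = 1.0
    return img
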