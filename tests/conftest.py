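import warnings

import numpy as np
import pytest

from gelmaquant import SceneSpec, generate_micrograph


@pytest.fixture(scope="session")
def small_scene():
    """A modest seeded scene with both viable and dead cells, shared read-only."""
    spec = SceneSpec(image_shape=(512, 512), n_cells=120, true_viability=0.9, rng_seed=7)
    stack, truths = generate_micrograph(spec)
    return spec, stack, truths


@pytest.fixture(scope="session")
def sparse_scene():
    """A scene whose nuclei are guaranteed isolated (separation >> 2 radii)."""
    spec = SceneSpec(
        image_shape=(512, 512),
        n_cells=40,
        true_viability=0.8,
        min_center_separation=45.0,
        rng_seed=13,
    )
    stack, truths = generate_micrograph(spec)
    return spec, stack, truths


def disk_mask(shape, centers, radius=10.0):
    """Boolean union of disks; shared helper for synthetic mask geometry."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    m = np.zeros(shape, bool)
    for cr, cc in centers:
        m |= (yy - cr) ** 2 + (xx - cc) ** 2 <= radius**2
    return m


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Pipeline warnings (weak contrast, small-sample caveats) are routine here."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield
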