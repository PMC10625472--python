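import numpy as np
import pytest

from tfmlab.synthetic import NoiseModel, make_scene, peak_to_total_counts, render_beads


@pytest.fixture(scope="session")
def default_scene():
    """Full-size study-conditions scene (512 px, 300 Pa dipole, one frame)."""
    return make_scene(rng_seed=7, n_t=1, drift_step_px=0.0)


@pytest.fixture(scope="session")
def small_scene():
    """A compact scene for cheap pipeline-level tests."""
    return make_scene(
        rng_seed=11,
        image_shape=(192, 192),
        separation_um=8.0,
        patch_sigma_um=1.2,
        n_t=2,
        n_z=5,
        n_adhesions=4,
    )


@pytest.fixture(scope="session")
def sparse_bead_images():
    """200 well-separated beads at default noise plus their true positions."""
    rng = np.random.default_rng(42)
    h, shape = 0.108, (256, 256)
    pts = []
    while len(pts) < 200:
        c = rng.uniform(8 * h, (shape[1] - 9) * h, 2)
        if all(np.hypot(c[0] - p[0], c[1] - p[1]) > 8 * h for p in pts):
            pts.append((float(c[0]), float(c[1])))
    pts = np.array(pts)
    tot = peak_to_total_counts(2000.0, 1.5)
    img = render_beads(pts, tot, 1.5 * h, shape, h, NoiseModel(), rng_seed=5)
    return img, pts
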