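import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from ensquant.simulate import NetworkSpec, RenderParams


@pytest.fixture(scope="session")
def small_render() -> RenderParams:
    """Benchmark-scale acquisition: 5 x 128 x 128 voxels."""
    return RenderParams(shape=(5, 128, 128))


@pytest.fixture(scope="session")
def small_spec() -> NetworkSpec:
    return NetworkSpec.control_small()


@pytest.fixture(scope="session")
def noiseless_render() -> RenderParams:
    """No blur, no noise, no background: intensities equal the support."""
    return RenderParams(
        shape=(7, 200, 200),
        psf_sigma_px=0.0,
        psf_sigma_z=0.0,
        photon_scale=np.inf,
        gauss_noise_sd=0.0,
        background_level=0.0,
    )


def random_thinned_patterns(n: int, size: int = 6, seed: int = 0):
    """Random small thinned skeletons (fixed points of the thinner)."""
    from skimage.morphology import skeletonize

    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        m = rng.random((size, size)) < rng.uniform(0.2, 0.8)
        sk = skeletonize(m)
        for _ in range(4):
            again = skeletonize(sk)
            if np.array_equal(again, sk):
                break
            sk = again
        else:
            continue
        if sk.any():
            out.append(sk)
    return out
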