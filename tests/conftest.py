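import dataclasses

import numpy as np
import pytest

from nucseg.synthetic_data import SynthParams, generate_image


@pytest.fixture(scope="session")
def easy_params() -> SynthParams:
    """Easy regime: 20 disjoint, well-separated nuclei, low noise."""
    return SynthParams(height=256, width=256, n_nuclei=20, noise_std=1.0, seed=7)


@pytest.fixture(scope="session")
def easy_pair(easy_params):
    """One synthetic (image, ground-truth mask) pair in the easy regime."""
    return generate_image(easy_params)


@pytest.fixture(scope="session")
def shifted_pair(easy_params):
    """The same scene rendered with a global stain shift."""
    params = dataclasses.replace(easy_params, stain_shift=(25.0, -15.0, 10.0))
    return generate_image(params)


def random_label_mask(
    rng: np.random.Generator, shape=(32, 32), max_instances=5
) -> np.ndarray:
    """Random blobby label mask with up to ``max_instances`` instances."""
    mask = np.zeros(shape, dtype=np.int32)
    n = rng.integers(0, max_instances + 1)
    for label in range(1, n + 1):
        cy, cx = rng.integers(0, shape[0]), rng.integers(0, shape[1])
        ry, rx = rng.integers(2, 7), rng.integers(2, 7)
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        inside = ((rr - cy) / ry) ** 2 + ((cc - cx) / rx) ** 2 <= 1.0
        mask[inside] = label
    return mask
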