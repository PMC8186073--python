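import numpy as np
import pytest
from scipy import ndimage

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def random_blob(shape=(48, 48), seed=0, n_disks=5, r_max=8):
    """Seeded hole-free single-component blob: union of random disks,
    largest 4-connected component kept, holes filled."""
    rng = np.random.default_rng(seed)
    mask = np.zeros(shape, dtype=bool)
    yy = np.arange(shape[0])[:, None]
    xx = np.arange(shape[1])[None, :]
    r_max = min(r_max, (min(shape) - 4) // 2)
    for _ in range(n_disks):
        r = int(rng.integers(2, max(3, r_max)))
        cr = int(rng.integers(r + 1, shape[0] - r - 1))
        cc = int(rng.integers(r + 1, shape[1] - r - 1))
        mask |= (yy - cr) ** 2 + (xx - cc) ** 2 <= r**2
    labels, n = ndimage.label(mask, structure=_CROSS)
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    largest = labels == (int(np.argmax(sizes)) + 1)
    return ndimage.binary_fill_holes(largest)


def random_mask_pair(shape=(32, 32), seed=0):
    """Pair of random masks including degenerate shapes for metric tests."""
    rng = np.random.default_rng(seed)
    kind = seed % 5
    if kind == 0:  # random blobs
        return random_blob(shape, seed), random_blob(shape, seed + 1)
    if kind == 1:  # 1-pixel gt
        gt = np.zeros(shape, bool)
        gt[rng.integers(shape[0]), rng.integers(shape[1])] = True
        return gt, random_blob(shape, seed + 1)
    if kind == 2:  # full gt
        return np.ones(shape, bool), random_blob(shape, seed + 1)
    if kind == 3:  # identical
        b = random_blob(shape, seed)
        return b, b.copy()
    gt = rng.random(shape) < 0.3
    gt[0, 0] = True  # keep gt nonempty
    pred = rng.random(shape) < 0.3
    return gt, pred


@pytest.fixture(scope="session")
def default_phantom():
    from amsmw.phantom import generate_phantom, phantom_params

    return generate_phantom(phantom_params(0))


@pytest.fixture(scope="session")
def segmented_phantom(default_phantom):
    """Fast-mode segmentation of the default phantom, shared across tests."""
    from amsmw.marked_watershed import amsmw_segment

    result = amsmw_segment(
        default_phantom.image, default_phantom.rroi, mode="fast", keep_candidates=True
    )
    return default_phantom, result
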