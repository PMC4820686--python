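import numpy as np
import pytest

from kidneyseg.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """The standard 20-slice phantom with ground truth and start rectangle."""
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def noisy_phantom():
    """High-noise phantom used to exercise the refinement path."""
    return generate_phantom(PhantomSpec(noise_sd=0.08))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_blob(rng, shape=(48, 48), n_disks=4, r_lo=4, r_hi=9):
    """A random single-component blob mask built from overlapping disks."""
    from skimage.measure import label

    m = np.zeros(shape, dtype=bool)
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    cr0 = rng.integers(shape[0] // 3, 2 * shape[0] // 3)
    cc0 = rng.integers(shape[1] // 3, 2 * shape[1] // 3)
    cr, ccen = cr0, cc0
    for _ in range(n_disks):
        r = rng.integers(r_lo, r_hi + 1)
        m |= (rr - cr) ** 2 + (cc - ccen) ** 2 <= r * r
        cr = int(np.clip(cr + rng.integers(-5, 6), r_hi, shape[0] - r_hi - 1))
        ccen = int(np.clip(ccen + rng.integers(-5, 6), r_hi, shape[1] - r_hi - 1))
    lab = label(m, connectivity=2)
    if lab.max() > 1:
        counts = np.bincount(lab.ravel())
        counts[0] = 0
        m = lab == counts.argmax()
    return m
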