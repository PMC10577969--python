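import numpy as np
import pytest

from priorseg import BinaryMask, PhantomParams, generate_case


def random_mask(rng, shape=(10, 10, 4), spacing=(1.0, 1.0, 5.0), p=0.2, label="PREDICTED"):
    """A random non-empty mask for property checks."""
    while True:
        vox = rng.random(shape) < p
        if vox.any():
            return BinaryMask(vox, spacing, label=label)


def sphere_mask(radius_mm, spacing, pad_mm=2.0, label="PT"):
    """A digital sphere centered on its own grid."""
    shape = tuple(
        2 * int(np.ceil((radius_mm + pad_mm) / s)) + 1 for s in spacing
    )
    center = tuple((n - 1) / 2 * s for n, s in zip(shape, spacing))
    idx = np.indices(shape, dtype=float)
    r2 = sum(((idx[a] * spacing[a] - center[a]) / radius_mm) ** 2 for a in range(3))
    return BinaryMask(r2 <= 1.0, spacing, label=label)


@pytest.fixture(scope="session")
def phantom_case():
    """One default phantom case shared by read-only tests."""
    return generate_case(PhantomParams(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
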